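import numpy as np
import pytest

from stancelab import (
    ConfigError,
    GREEN,
    RED,
    YELLOW,
    classification_report,
    feature_matrix,
    fit_lda,
    predict_lda,
    prf_from_counts,
    split_cohort,
)
from stancelab.label_classifier import discriminant_scores, report_to_frame


class TestSplitCohort:
    def test_sizes_by_rounding(self):
        train, test = split_cohort(list(range(10)), 0.8, seed=1)
        assert (len(train), len(test)) == (8, 2)

    def test_explicit_count_622(self):
        train, test = split_cohort(list(range(622)), 0.8, seed=1,
                                   explicit_train_count=500)
        assert (len(train), len(test)) == (500, 122)

    def test_disjoint_exhaustive(self):
        items = [f"r{i}" for i in range(37)]
        train, test = split_cohort(items, 0.8, seed=5)
        assert sorted(train + test) == sorted(items)
        assert not set(train) & set(test)

    def test_deterministic_per_seed(self):
        items = list(range(100))
        a = split_cohort(items, 0.8, seed=3)
        b = split_cohort(items, 0.8, seed=3)
        c = split_cohort(items, 0.8, seed=4)
        assert a == b
        assert a != c

    def test_stratified_preserves_class_fractions(self):
        items = list(range(100))
        labels = [GREEN] * 80 + [RED] * 20
        train, test = split_cohort(items, 0.8, seed=0, stratify=labels)
        train_labels = [labels[i] for i in train]
        assert train_labels.count(GREEN) == 64
        assert train_labels.count(RED) == 16

    def test_empty_cohort(self):
        with pytest.raises(ValueError):
            split_cohort([], 0.8, seed=0)

    def test_bad_fraction(self):
        with pytest.raises(ConfigError):
            split_cohort([1, 2], 1.5, seed=0)


class TestFitLda:
    def test_two_class_hand_arithmetic(self):
        X = np.array([-2.2, -2.0, -1.8, 1.8, 2.0, 2.2])
        y = ["a"] * 3 + ["b"] * 3
        model = fit_lda(X, y)
        np.testing.assert_allclose(model.class_means.ravel(), [-2.0, 2.0])
        # scatter = 2 * (0.04 + 0 + 0.04) = 0.16 ; / (6 - 2) = 0.04
        assert model.pooled_covariance[0, 0] == pytest.approx(0.04)
        np.testing.assert_allclose(np.exp(model.log_priors), [0.5, 0.5])

    def test_empirical_priors_from_imbalanced_counts(self):
        rng = np.random.default_rng(0)
        counts = {GREEN: 419, YELLOW: 75, RED: 6}
        X, y = [], []
        for i, (lab, n) in enumerate(counts.items()):
            X.append(rng.normal(i * 10, 1.0, size=(n, 2)))
            y += [lab] * n
        model = fit_lda(np.vstack(X), y)
        np.testing.assert_allclose(
            np.exp(model.log_priors), [0.838, 0.150, 0.012], atol=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((5, 2)), ["a"] * 5)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="'b'"):
            fit_lda(np.arange(8.0), ["a"] * 7 + ["b"])

    def test_duplicated_column_handled_by_ridge(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))])
        y = ["a"] * 30 + ["b"] * 30
        base = fit_lda(X, y)
        dup = fit_lda(np.hstack([X, X[:, :1]]), y)
        assert dup.ridge > 0
        pred_base = predict_lda(base, X)
        pred_dup = predict_lda(dup, np.hstack([X, X[:, :1]]))
        np.testing.assert_array_equal(pred_base, pred_dup)


class TestPredictLda:
    def _two_class_model(self):
        X = np.array([-2.2, -2.0, -1.8, 1.8, 2.0, 2.2])
        return fit_lda(X, ["a"] * 3 + ["b"] * 3)

    def test_discriminant_arithmetic(self):
        model = self._two_class_model()
        # delta_a(1) = -50 - 50 = -100, delta_b(1) = 50 - 50 = 0
        scores = discriminant_scores(model, np.array([[1.0]]))
        log_half = np.log(0.5)
        np.testing.assert_allclose(scores[0], [-100 + log_half, 0 + log_half])
        assert predict_lda(model, np.array([[1.0]]))[0] == "b"

    def test_equidistant_tie_breaks_to_first_class(self):
        model = self._two_class_model()
        assert predict_lda(model, np.array([[0.0]]))[0] == "a"

    def test_identical_means_predicts_argmax_prior(self):
        rng = np.random.default_rng(1)
        Xa = rng.normal(0, 1, size=(40, 2))
        Xb = rng.normal(0, 1, size=(10, 2))
        model = fit_lda(np.vstack([Xa, Xb]), ["a"] * 40 + ["b"] * 10)
        model.class_means[1] = model.class_means[0]  # force identical geometry
        preds = predict_lda(model, rng.normal(size=(50, 2)))
        assert (preds == "a").all()

    def test_dimension_mismatch(self):
        model = self._two_class_model()
        with pytest.raises(ValueError):
            predict_lda(model, np.zeros((3, 4)))

    def test_oracle_equivalence_random_instances(self):
        # brute-force per-class Gaussian discriminant with an explicit
        # inverse must agree with the solve-based linear scores
        rng = np.random.default_rng(123)
        for trial in range(20):
            d = int(rng.integers(1, 6))
            k = int(rng.integers(2, 5))
            means = rng.normal(0, 3, size=(k, d))
            X, y = [], []
            for i in range(k):
                n_i = int(rng.integers(5, 30))
                X.append(means[i] + rng.normal(0, 1, size=(n_i, d)))
                y += [f"c{i}"] * n_i
            X = np.vstack(X)
            model = fit_lda(X, y)
            query = rng.normal(0, 3, size=(100, d))
            pred = predict_lda(model, query)

            inv = np.linalg.inv(model.pooled_covariance)
            oracle = []
            for x in query:
                best, best_score = None, -np.inf
                for i, cls in enumerate(model.classes):
                    diff = x - model.class_means[i]
                    score = model.log_priors[i] - 0.5 * diff @ inv @ diff
                    if score > best_score:
                        best, best_score = cls, score
                oracle.append(best)
            np.testing.assert_array_equal(pred, np.array(oracle))

    def test_separated_gaussians_high_accuracy(self):
        rng = np.random.default_rng(5)
        mu = np.zeros(3)
        mu2 = np.full(3, 10.0 / np.sqrt(3))  # ||mu1 - mu2|| = 10 sigma
        Xtr = np.vstack(
            [rng.normal(mu, 1, (200, 3)), rng.normal(mu2, 1, (200, 3))]
        )
        ytr = ["a"] * 200 + ["b"] * 200
        model = fit_lda(Xtr, ytr)
        Xte = np.vstack(
            [rng.normal(mu, 1, (200, 3)), rng.normal(mu2, 1, (200, 3))]
        )
        yte = np.array(["a"] * 200 + ["b"] * 200)
        acc = np.mean(predict_lda(model, Xte) == yte)
        assert acc >= 0.99

    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        true_means = np.array([[0.0, 0.0], [2.0, -1.0]])
        sigma = 1.0
        n = 1000
        X = np.vstack(
            [rng.normal(m, sigma, size=(n, 2)) for m in true_means]
        )
        y = ["a"] * n + ["b"] * n
        model = fit_lda(X, y)
        se = 3 * sigma / np.sqrt(n)
        assert np.all(np.abs(model.class_means - true_means) < se)


class TestClassificationReport:
    def test_perfect(self):
        y = [GREEN, YELLOW, RED, GREEN]
        rep = classification_report(y, y)
        assert rep.accuracy == 100.0
        assert all(v["f_score"] == 100.0 for v in rep.per_class.values())
        assert np.trace(rep.confusion) == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classification_report([GREEN], [GREEN, RED])

    def test_absent_metrics_for_unpredicted_class(self):
        y_true = [GREEN] * 5 + [RED] * 2
        y_pred = [GREEN] * 7
        rep = classification_report(y_true, y_pred)
        assert rep.per_class[RED]["precision"] is None
        assert rep.per_class[RED]["recall"] == 0.0
        assert rep.per_class[RED]["f_score"] is None

    def test_merge_never_decreases_accuracy_for_gy_confusion(self):
        # all off-diagonal mass between Green and Yellow
        y_true = [GREEN] * 6 + [YELLOW] * 4 + [RED] * 2
        y_pred = [GREEN] * 4 + [YELLOW] * 2 + [GREEN] * 3 + [YELLOW] * 1 + [RED] * 2
        rep = classification_report(y_true, y_pred, merge=(GREEN, YELLOW))
        assert rep.merged.accuracy >= rep.accuracy
        assert "Green+Yellow" in rep.merged.labels

    def test_report_frame_shape(self):
        y_true = [GREEN] * 6 + [YELLOW] * 4
        y_pred = [GREEN] * 5 + [YELLOW] * 5
        rep = classification_report(y_true, y_pred, merge=(GREEN, YELLOW))
        frame = report_to_frame(rep, "hip")
        assert set(frame.columns) == {
            "joint", "label", "actual", "predicted", "matched", "f_score",
            "accuracy",
        }
        assert frame["matched"].iloc[:2].sum() == np.trace(rep.confusion)


class TestPrfFromCounts:
    def test_zero_denominator_rule(self):
        out = prf_from_counts(0, 0, 5, 100)
        assert out["precision"] is None
        assert out["recall"] == 0.0
        assert out["f_score"] is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            prf_from_counts(10, 5, 20, 100)

    def test_simple_arithmetic(self):
        out = prf_from_counts(50, 100, 50, 200, other_diagonal=100)
        assert out["precision"] == pytest.approx(50.0)
        assert out["recall"] == pytest.approx(100.0)
        assert out["f_score"] == pytest.approx(200.0 / 3.0)
        assert out["accuracy"] == pytest.approx(75.0)


class TestFeatureMatrix:
    def test_shape_and_names(self, cohort300, template_reference):
        records = cohort300[0][:10]
        X, names = feature_matrix(records, template_reference)
        assert X.shape == (10, 13)
        assert names[-1] == "GPS"
        assert names[0] == "PelvicTilt_MAX"
        X2, names2 = feature_matrix(records, include_gps=False)
        assert X2.shape == (10, 12)
        np.testing.assert_allclose(X[:, :12], X2)

    def test_gps_requires_reference(self, cohort300):
        with pytest.raises(ConfigError):
            feature_matrix(cohort300[0][:2], None, include_gps=True)
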