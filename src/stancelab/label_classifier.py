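"""Linear-discriminant feasibility classifier.

Maps per-record kinematic feature vectors ({MAX, ROM, MEAN} per sagittal
variable, optionally plus GPS) to moment labels, with an 80/20 split,
empirical class priors, a pooled within-class covariance, and confusion /
accuracy / per-class F-score reporting including the Green+Yellow merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ReferenceProfile, SAGITTAL_VARIABLES, SubjectRecord
from .exceptions import ConfigError
from .kinematic_features import FEATURE_NAMES, curve_features, gait_profile_score
from .kinetics_labeling import LABEL_ORDER

DEFAULT_RIDGE_SCALE = 1e-8
_COND_LIMIT = 1e10


def feature_matrix(
    records: Sequence[SubjectRecord],
    reference: ReferenceProfile | None = None,
    variable_set: Sequence[str] | None = None,
    include_gps: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build the per-record feature matrix.

    Returns (X, feature_names) with one row per record: MAX/ROM/MEAN for
    each kinematic variable, plus GPS as the last column when
    ``include_gps`` (requires ``reference``).
    """
    variables = tuple(variable_set) if variable_set is not None else SAGITTAL_VARIABLES
    if include_gps and reference is None:
        raise ConfigError("include_gps=True requires a reference profile")
    names = [f"{var}_{feat}" for var in variables for feat in FEATURE_NAMES]
    if include_gps:
        names.append("GPS")
    rows = []
    for rec in records:
        row = []
        for var in variables:
            feats = curve_features(rec.kinematics[var])
            row.extend(feats[f] for f in FEATURE_NAMES)
        if include_gps:
            row.append(gait_profile_score(rec, reference, variables))
        rows.append(row)
    X = np.array(rows, dtype=float).reshape(len(rows), len(names))
    return X, names


def split_cohort(
    records: Sequence,
    train_fraction: float = 0.8,
    seed: int = 0,
    explicit_train_count: int | None = None,
    stratify: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test partition.

    Sizes are ``round(n * train_fraction)`` unless ``explicit_train_count``
    is given.  With ``stratify`` (a label per record) the rounding is
    applied per class.  Reproducible for a fixed seed.
    """
    records = list(records)
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    if not (0.0 < train_fraction < 1.0):
        raise ConfigError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if explicit_train_count is not None and not (0 <= explicit_train_count <= n):
        raise ConfigError(
            f"explicit_train_count {explicit_train_count} out of range for n={n}"
        )
    rng = np.random.default_rng(seed)
    if stratify is not None:
        if len(stratify) != n:
            raise ConfigError("stratify must provide one label per record")
        if explicit_train_count is not None:
            raise ConfigError("explicit_train_count is incompatible with stratify")
        labels = np.asarray(stratify)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for lab in pd.unique(labels):
            idx = np.flatnonzero(labels == lab)
            idx = rng.permutation(idx)
            k = int(round(idx.size * train_fraction))
            train_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
        train_idx.sort()
        test_idx.sort()
    else:
        k = (
            explicit_train_count
            if explicit_train_count is not None
            else int(round(n * train_fraction))
        )
        perm = rng.permutation(n)
        train_idx = sorted(perm[:k].tolist())
        test_idx = sorted(perm[k:].tolist())
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


@dataclass
class LDAModel:
    classes: tuple[str, ...]
    class_means: np.ndarray  # (k, d)
    pooled_covariance: np.ndarray  # (d, d)
    log_priors: np.ndarray  # (k,)
    ridge: float = 0.0
    feature_names: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": np.exp(self.log_priors).tolist(),
            "ridge": self.ridge,
            "feature_names": list(self.feature_names or []),
        }


def _default_class_order(labels: np.ndarray) -> tuple[str, ...]:
    uniq = set(str(x) for x in labels)
    if uniq <= set(LABEL_ORDER):
        return tuple(l for l in LABEL_ORDER if l in uniq)
    return tuple(sorted(uniq))


def fit_lda(
    features: np.ndarray,
    labels: Sequence[str],
    class_order: Sequence[str] | None = None,
    ridge_scale: float = DEFAULT_RIDGE_SCALE,
    feature_names: Sequence[str] | None = None,
) -> LDAModel:
    """Fit a linear discriminant model.

    Class means are per-class averages, the pooled covariance is the
    within-class scatter divided by (n - k), priors are empirical, and a
    diagonal ridge (``ridge_scale * mean diagonal``) is added only when the
    pooled covariance is ill-conditioned, escalating tenfold until the
    discriminant is solvable.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray([str(l) for l in labels])
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    classes = (
        tuple(class_order) if class_order is not None else _default_class_order(y)
    )
    if len(classes) < 2:
        raise ValueError(
            f"need at least 2 classes to fit a discriminant, got {classes}"
        )
    n, d = X.shape
    k = len(classes)
    means = np.zeros((k, d))
    scatter = np.zeros((d, d))
    counts = np.zeros(k, dtype=int)
    for i, cls in enumerate(classes):
        Xc = X[y == cls]
        if Xc.shape[0] < 2:
            raise ValueError(
                f"class {cls!r} has {Xc.shape[0]} training record(s); "
                f"need >= 2"
            )
        counts[i] = Xc.shape[0]
        means[i] = Xc.mean(axis=0)
        centered = Xc - means[i]
        scatter += centered.T @ centered
    if counts.sum() != n:
        raise ValueError(
            "labels contain classes outside the requested class order"
        )
    cov = scatter / (n - k)

    ridge = 0.0
    base = float(np.mean(np.diag(cov))) or 1.0
    attempt = cov
    for _ in range(20):
        cond = np.linalg.cond(attempt)
        if np.isfinite(cond) and cond < _COND_LIMIT:
            break
        ridge = ridge_scale * base if ridge == 0.0 else ridge * 10.0
        attempt = cov + ridge * np.eye(d)
    cov = attempt

    priors = counts / n
    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_covariance=cov,
        log_priors=np.log(priors),
        ridge=ridge,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def discriminant_scores(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Linear discriminant delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2
    + log pi_k, for each class; shape (n, k)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :] if X.size == model.n_features else X[:, None]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    A = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # (d, k)
    const = -0.5 * np.einsum("kd,dk->k", model.class_means, A) + model.log_priors
    return X @ A + const


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Assign each record the class maximizing the linear discriminant;
    exact ties break toward the earlier class in ``model.classes``."""
    scores = discriminant_scores(model, features)
    idx = np.argmax(scores, axis=1)  # argmax returns the first maximum
    return np.asarray(model.classes)[idx]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    labels: tuple[str, ...]
    confusion: np.ndarray  # (true, predicted) counts
    n_test: int
    accuracy: float  # percent
    per_class: dict[str, dict[str, float | None]] = field(default_factory=dict)
    merged: "ClassifierReport | None" = None

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(self.labels, name="true"),
            columns=pd.Index(self.labels, name="predicted"),
        )


def _prf(tp: int, predicted_total: int, actual_total: int) -> dict[str, float | None]:
    precision = 100.0 * tp / predicted_total if predicted_total > 0 else None
    recall = 100.0 * tp / actual_total if actual_total > 0 else None
    if precision is None or recall is None:
        f_score = None
    elif precision + recall == 0.0:
        f_score = 0.0
    else:
        f_score = 2.0 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f_score": f_score}


def prf_from_counts(
    tp: int,
    predicted_total: int,
    actual_total: int,
    n: int,
    other_diagonal: int = 0,
) -> dict[str, float | None]:
    """Precision / recall / F-score / accuracy (percent) from confusion
    marginals, so published per-class counts can be rechecked without the
    full matrix.  ``other_diagonal`` is the correct-count contribution of
    the remaining classes.  Zero denominators yield ``None`` metrics."""
    if not (0 <= tp <= min(predicted_total, actual_total) <= n):
        raise ValueError(
            f"inconsistent counts: tp={tp}, predicted={predicted_total}, "
            f"actual={actual_total}, n={n}"
        )
    out = _prf(tp, predicted_total, actual_total)
    out["accuracy"] = 100.0 * (tp + other_diagonal) / n if n > 0 else None
    return out


def _merge_labels(y: np.ndarray, merge: Sequence[str]) -> tuple[np.ndarray, str]:
    merge_set = set(merge)
    merged_name = "+".join(l for l in LABEL_ORDER if l in merge_set) or "+".join(
        sorted(merge_set)
    )
    out = np.array([merged_name if v in merge_set else v for v in y])
    return out, merged_name


def classification_report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] | None = None,
    merge: Sequence[str] | None = None,
) -> ClassifierReport:
    """Confusion counts, accuracy and one-vs-rest precision/recall/F per
    class.  With ``merge`` (e.g. {Green, Yellow}) a second report on the
    pooled relabeling is attached as ``.merged``."""
    y_true = np.asarray([str(v) for v in true_labels])
    y_pred = np.asarray([str(v) for v in predicted_labels])
    if y_true.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    if labels is None:
        present = set(y_true) | set(y_pred)
        ordered = [l for l in LABEL_ORDER if l in present]
        ordered += sorted(present - set(ordered))
        labels = tuple(ordered)
    else:
        labels = tuple(labels)
    index = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    n = int(y_true.size)
    accuracy = 100.0 * float(np.trace(confusion)) / n if n else 0.0
    per_class = {}
    for i, lab in enumerate(labels):
        per_class[lab] = _prf(
            tp=int(confusion[i, i]),
            predicted_total=int(confusion[:, i].sum()),
            actual_total=int(confusion[i, :].sum()),
        )
    report = ClassifierReport(
        labels=labels,
        confusion=confusion,
        n_test=n,
        accuracy=accuracy,
        per_class=per_class,
    )
    if merge:
        mt, _ = _merge_labels(y_true, merge)
        mp, _ = _merge_labels(y_pred, merge)
        report.merged = classification_report(mt, mp)
    return report


def report_to_frame(report: ClassifierReport, joint: str = "") -> pd.DataFrame:
    """Flatten a report into the published table shape: per label the
    rule-based (actual) count, the model-predicted count, the matched
    (diagonal) count, F-score and accuracy; merged rows appended."""
    rows = []
    for i, lab in enumerate(report.labels):
        rows.append(
            {
                "joint": joint,
                "label": lab,
                "actual": int(report.confusion[i, :].sum()),
                "predicted": int(report.confusion[:, i].sum()),
                "matched": int(report.confusion[i, i]),
                "f_score": report.per_class[lab]["f_score"],
                "accuracy": report.accuracy if i == 0 else np.nan,
            }
        )
    if report.merged is not None:
        sub = report_to_frame(report.merged, joint)
        sub["label"] = "merged:" + sub["label"]
        rows.extend(sub.to_dict("records"))
    return pd.DataFrame(rows)
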