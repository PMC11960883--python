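"""Label-group statistics (one-way ANOVA, Bonferroni-corrected pairwise
t-tests) and assembly of the full report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .cohort_io import SubjectRecord, write_cohort
from .exceptions import ConfigError
from .kinetics_labeling import (
    LABEL_ORDER,
    LabelSummary,
    MomentLabelResult,
    labels_to_frame,
)
from .label_classifier import ClassifierReport, report_to_frame

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: decimals used when reporting the Bonferroni-corrected alpha (0.05/3 -> 0.017)
DEFAULT_ALPHA_DIGITS = 3


def anova_oneway(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Classic equal-variance one-way ANOVA over >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} values; need >= 2")
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if not within > 0.0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    f_statistic, p = _st.f_oneway(*arrays)
    return {"f_statistic": float(f_statistic), "p": float(p)}


@dataclass
class GroupComparisonResult:
    group_names: tuple[str, ...]
    f_statistic: float
    anova_p: float
    pairwise: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    corrected_alpha: float = 0.017
    significant: dict[tuple[str, str], bool] = field(default_factory=dict)

    def to_frame(self, joint: str = "") -> pd.DataFrame:
        rows = []
        for pair, res in self.pairwise.items():
            rows.append(
                {
                    "joint": joint,
                    "pair": f"{pair[0]} vs. {pair[1]}",
                    "statistic": res["statistic"],
                    "p": res["p"],
                    "corrected_alpha": self.corrected_alpha,
                    "significant": self.significant[pair],
                }
            )
        return pd.DataFrame(rows)


def bonferroni_pairwise(
    groups: Sequence[Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    group_names: Sequence[str] | None = None,
    equal_var: bool = True,
    round_digits: int | None = DEFAULT_ALPHA_DIGITS,
) -> GroupComparisonResult:
    """ANOVA plus all pairwise two-sample t-tests at a Bonferroni-corrected
    alpha (``alpha / n_pairs``, rounded to ``round_digits`` for reporting
    and significance calls — three groups at 0.05 give 0.017)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    names = (
        tuple(group_names)
        if group_names is not None
        else tuple(f"group{i}" for i in range(len(arrays)))
    )
    if len(names) != len(arrays):
        raise ConfigError("group_names length must match groups")
    overall = anova_oneway(arrays)
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    corrected = alpha / n_pairs
    if round_digits is not None:
        corrected = round(corrected, round_digits)
    result = GroupComparisonResult(
        group_names=names,
        f_statistic=overall["f_statistic"],
        anova_p=overall["p"],
        alpha=alpha,
        corrected_alpha=corrected,
    )
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            t, p = _st.ttest_ind(arrays[i], arrays[j], equal_var=equal_var)
            pair = (names[i], names[j])
            result.pairwise[pair] = {"statistic": float(t), "p": float(p)}
            result.significant[pair] = bool(p < corrected)
    return result


def nrmse_by_label(
    label_results: Sequence[MomentLabelResult],
    min_group_size: int = 2,
) -> tuple[list[str], list[np.ndarray]]:
    """Group per-record nRMSE values by label (canonical order), dropping
    labels with fewer than ``min_group_size`` members."""
    names, groups = [], []
    for label in LABEL_ORDER:
        vals = np.array([r.nrmse for r in label_results if r.label == label])
        if vals.size >= min_group_size:
            names.append(label)
            groups.append(vals)
    return names, groups


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

REPORT_FILES = (
    "labels.csv",
    "table1_label_summary.csv",
    "table2_features_by_label.csv",
    "table3_classifier.csv",
    "fig3_nrmse_histograms.csv",
    "fig5_subphase_profiles.csv",
)
MANIFEST_FILE = "manifest.json"


def _histogram_frame(
    label_results: Mapping[str, Sequence[MomentLabelResult]],
    n_bins: int = 30,
) -> pd.DataFrame:
    all_vals = [
        r.nrmse for results in label_results.values() for r in results
    ]
    hi = max(0.6, float(np.max(all_vals))) if all_vals else 0.6
    edges = np.linspace(0.0, hi, n_bins + 1)
    rows = []
    for joint, results in label_results.items():
        for label in LABEL_ORDER:
            vals = np.array([r.nrmse for r in results if r.label == label])
            counts, _ = np.histogram(vals, bins=edges)
            for b in range(n_bins):
                rows.append(
                    {
                        "joint": joint,
                        "label": label,
                        "bin_left": edges[b],
                        "bin_right": edges[b + 1],
                        "count": int(counts[b]),
                    }
                )
    return pd.DataFrame(rows)


def build_report(
    records: Sequence[SubjectRecord],
    labels: Mapping[str, tuple[Sequence[MomentLabelResult], LabelSummary]],
    features: Mapping[str, pd.DataFrame],
    subphase_profiles: Mapping[str, pd.DataFrame],
    classifier_reports: Mapping[str, ClassifierReport],
    comparisons: Mapping[str, GroupComparisonResult],
    out_dir: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the report bundle: per-record labels, the three summary
    tables, histogram data, subphase profiles, and a manifest.  All maps
    are keyed by joint.  Deterministic given identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    label_rows = pd.concat(
        [labels_to_frame(results) for results, _ in labels.values()],
        ignore_index=True,
    )
    paths["labels"] = out / "labels.csv"
    label_rows.to_csv(paths["labels"], index=False)

    t1_parts = []
    for joint, (_, summary) in labels.items():
        frame = summary.to_frame()
        frame["excluded"] = summary.excluded
        t1_parts.append(frame)
        if joint in comparisons:
            comp = comparisons[joint].to_frame(joint)
            comp["label"] = comp["pair"].map(lambda s: f"p-value ({s})")
            t1_parts.append(comp)
    table1 = pd.concat(t1_parts, ignore_index=True)
    paths["table1"] = out / "table1_label_summary.csv"
    table1.to_csv(paths["table1"], index=False)

    table2 = pd.concat(list(features.values()), ignore_index=True)
    paths["table2"] = out / "table2_features_by_label.csv"
    table2.to_csv(paths["table2"], index=False)

    table3 = pd.concat(
        [report_to_frame(rep, joint) for joint, rep in classifier_reports.items()],
        ignore_index=True,
    )
    paths["table3"] = out / "table3_classifier.csv"
    table3.to_csv(paths["table3"], index=False)

    paths["fig3"] = out / "fig3_nrmse_histograms.csv"
    _histogram_frame({j: res for j, (res, _) in labels.items()}).to_csv(
        paths["fig3"], index=False
    )

    paths["fig5"] = out / "fig5_subphase_profiles.csv"
    pd.concat(list(subphase_profiles.values()), ignore_index=True).to_csv(
        paths["fig5"], index=False
    )

    manifest = {
        "n_records": len(records),
        "joints": sorted(labels.keys()),
        "seed": seed,
        "config": dict(config) if config else {},
        "files": [p.name for p in paths.values()],
    }
    paths["manifest"] = out / MANIFEST_FILE
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def run_full_analysis(
    records: Sequence[SubjectRecord],
    reference,
    out_dir: str | Path | None = None,
    *,
    seed: int = 0,
    train_fraction: float = 0.8,
    joints: Sequence[str] | None = None,
    variable_set: Sequence[str] | None = None,
    include_gps: bool = True,
    merge_green_yellow: bool = True,
    alpha: float = DEFAULT_ALPHA,
    config: Mapping | None = None,
) -> dict:
    """End-to-end pipeline on an in-memory cohort.

    Labels every joint, summarizes kinematic features per label, fits one
    LDA per joint on a single shared train/test split, runs the label-wise
    nRMSE comparisons, and (optionally) writes the report bundle.
    Training classes with fewer than two members are dropped from the
    discriminant fit with a warning.
    """
    from .kinematic_features import features_by_label, subphase_error_profile
    from .kinetics_labeling import label_cohort
    from .label_classifier import (
        classification_report,
        feature_matrix,
        fit_lda,
        predict_lda,
        split_cohort,
    )

    records = list(records)
    use_joints = tuple(joints) if joints is not None else ("hip", "knee", "ankle")

    train, test = split_cohort(records, train_fraction=train_fraction, seed=seed)
    X_train, feature_names = feature_matrix(
        train, reference, variable_set, include_gps
    )
    X_test, _ = feature_matrix(test, reference, variable_set, include_gps)

    labels_out: dict = {}
    features_out: dict = {}
    subphase_out: dict = {}
    reports_out: dict = {}
    comparisons_out: dict = {}
    for joint in use_joints:
        results, summary = label_cohort(records, joint)
        labels_out[joint] = (results, summary)
        features_out[joint] = features_by_label(
            records, results, joint, reference, variable_set
        )
        subphase_out[joint] = subphase_error_profile(records, results, joint)

        names, groups = nrmse_by_label(results)
        if len(groups) >= 2:
            comparisons_out[joint] = bonferroni_pairwise(
                groups, alpha=alpha, group_names=names
            )

        lmap = {(r.subject_id, r.side): r.label for r in results}
        y_train = np.array(
            [lmap.get((r.subject_id, r.side), "") for r in train]
        )
        y_test = np.array([lmap.get((r.subject_id, r.side), "") for r in test])
        keep_tr = y_train != ""
        keep_te = y_test != ""
        counts = pd.Series(y_train[keep_tr]).value_counts()
        usable = [c for c in counts.index if counts[c] >= 2]
        dropped = [c for c in counts.index if counts[c] < 2]
        if dropped:
            logger.warning(
                "%s: dropping training class(es) %s with < 2 records",
                joint,
                dropped,
            )
        fit_mask = keep_tr & np.isin(y_train, usable)
        if len(usable) >= 2 and keep_te.sum() > 0:
            model = fit_lda(
                X_train[fit_mask],
                y_train[fit_mask],
                feature_names=feature_names,
            )
            y_pred = predict_lda(model, X_test[keep_te])
            reports_out[joint] = classification_report(
                y_test[keep_te],
                y_pred,
                merge=("Green", "Yellow") if merge_green_yellow else None,
            )

    out = {
        "labels": labels_out,
        "features": features_out,
        "subphase_profiles": subphase_out,
        "classifier_reports": reports_out,
        "comparisons": comparisons_out,
        "split": (train, test),
        "feature_names": feature_names,
    }
    if out_dir is not None:
        out["paths"] = build_report(
            records,
            labels_out,
            features_out,
            subphase_out,
            reports_out,
            comparisons_out,
            out_dir,
            config=config,
            seed=seed,
        )
    return out
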