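"""Kinematic feature extraction: MAX/ROM/MEAN per variable, the Gait
Profile Score against a reference, label-conditioned summaries, and the
five-subphase decomposition of moment prediction error."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    CANONICAL_N,
    ReferenceProfile,
    SAGITTAL_VARIABLES,
    StanceCurve,
    SubjectRecord,
)
from .exceptions import CohortValidationError, ConfigError
from .kinetics_labeling import LABEL_ORDER, MomentLabelResult, _values, nrmse

FEATURE_NAMES = ("MAX", "ROM", "MEAN")

DEFAULT_N_SUBPHASES = 5


def curve_features(curve) -> dict[str, float]:
    """MAX, ROM (max - min) and MEAN of a curve over stance."""
    v = _values(curve)
    vmax = float(np.max(v))
    vmin = float(np.min(v))
    return {"MAX": vmax, "ROM": vmax - vmin, "MEAN": float(np.mean(v))}


def gait_variable_scores(
    record: SubjectRecord,
    reference: ReferenceProfile,
    variable_set: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-variable RMS deviation of the record from the reference mean
    curve."""
    variables = tuple(variable_set) if variable_set is not None else SAGITTAL_VARIABLES
    scores: dict[str, float] = {}
    for var in variables:
        if var not in record.kinematics:
            raise CohortValidationError(
                f"subject {record.subject_id!r} side {record.side!r}: "
                f"missing kinematic variable {var!r}"
            )
        if var not in reference.mean_curves:
            raise CohortValidationError(
                f"reference profile is missing variable {var!r}"
            )
        diff = record.kinematics[var].values - reference.mean_curves[var].values
        scores[var] = float(np.sqrt(np.mean(diff**2)))
    return scores


def gait_profile_score(
    record: SubjectRecord,
    reference: ReferenceProfile,
    variable_set: Sequence[str] | None = None,
) -> float:
    """Gait Profile Score: RMS over the per-variable RMS deviations.

    Zero iff the record matches the reference exactly on every variable;
    equals d/sqrt(k) when exactly one of k variables is offset by a
    constant d.
    """
    scores = gait_variable_scores(record, reference, variable_set)
    gvs = np.array(list(scores.values()))
    return float(np.sqrt(np.mean(gvs**2)))


def _label_map(label_results: Iterable[MomentLabelResult]) -> dict[tuple[str, str], str]:
    return {(r.subject_id, r.side): r.label for r in label_results}


def features_by_label(
    records: Sequence[SubjectRecord],
    label_results: Sequence[MomentLabelResult],
    joint: str,
    reference: ReferenceProfile,
    variable_set: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean +/- sd of each kinematic feature (and GPS) per moment label.

    Returns a tidy frame with columns
    ``joint, label, n, variable, feature, mean, sd``; labels follow the
    canonical Green/Yellow/Red order, restricted to labels present.
    Records without a label for this joint (e.g. excluded as degenerate)
    are skipped.
    """
    variables = tuple(variable_set) if variable_set is not None else SAGITTAL_VARIABLES
    lmap = _label_map(label_results)

    per_label: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        label = lmap.get((rec.subject_id, rec.side))
        if label is None:
            continue
        bucket = per_label.setdefault(label, {})
        for var in variables:
            feats = curve_features(rec.kinematics[var])
            for feat in FEATURE_NAMES:
                bucket.setdefault(f"{var}:{feat}", []).append(feats[feat])
        bucket.setdefault("GPS:GPS", []).append(
            gait_profile_score(rec, reference, variables)
        )

    rows = []
    for label in LABEL_ORDER:
        if label not in per_label:
            continue
        bucket = per_label[label]
        n = len(bucket["GPS:GPS"])
        for key in list(bucket):
            var, feat = key.split(":")
            vals = np.array(bucket[key])
            rows.append(
                {
                    "joint": joint,
                    "label": label,
                    "n": n,
                    "variable": var,
                    "feature": feat,
                    "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def subphase_nrmse(
    measured,
    predicted,
    n_subphases: int = DEFAULT_N_SUBPHASES,
) -> np.ndarray:
    """Per-subphase nRMSE: RMSE restricted to each contiguous bin of the
    stance, normalized by the *full-stance* measured peak-to-peak (so bins
    remain comparable when mid-stance ranges are small)."""
    m = _values(measured)
    p = _values(predicted)
    if m.size % n_subphases != 0:
        raise ConfigError(
            f"{m.size} samples not divisible into {n_subphases} subphases"
        )
    p2p = float(np.max(m) - np.min(m))
    if not p2p > 0.0:
        from .exceptions import DegenerateTraceError

        raise DegenerateTraceError("flat measured trace in subphase profile")
    sq = (m - p) ** 2
    bins = sq.reshape(n_subphases, -1)
    return np.sqrt(bins.mean(axis=1)) / p2p


def subphase_error_profile(
    records: Sequence[SubjectRecord],
    label_results: Sequence[MomentLabelResult],
    joint: str,
    n_subphases: int = DEFAULT_N_SUBPHASES,
) -> pd.DataFrame:
    """Median and quartiles of per-record subphase nRMSE, per label.

    Columns: ``joint, label, subphase (1-based), median, q1, q3``.
    """
    if CANONICAL_N % n_subphases != 0:
        raise ConfigError(
            f"{CANONICAL_N} samples not divisible into {n_subphases} subphases"
        )
    lmap = _label_map(label_results)
    per_label: dict[str, list[np.ndarray]] = {}
    for rec in records:
        label = lmap.get((rec.subject_id, rec.side))
        if label is None:
            continue
        per_label.setdefault(label, []).append(
            subphase_nrmse(
                rec.measured_moments[joint],
                rec.predicted_moments[joint],
                n_subphases,
            )
        )

    rows = []
    for label in LABEL_ORDER:
        if label not in per_label:
            continue
        mat = np.vstack(per_label[label])  # records x bins
        q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=0)
        for b in range(n_subphases):
            rows.append(
                {
                    "joint": joint,
                    "label": label,
                    "subphase": b + 1,
                    "median": float(med[b]),
                    "q1": float(q1[b]),
                    "q3": float(q3[b]),
                }
            )
    return pd.DataFrame(rows)
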