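"""Moment-prediction error labeling.

Each measured moment trace defines its own acceptance band: the
standardized peak ``(max - mean) / sd`` of the trace sets a lower and an
upper kinetic limit (10% and 20% of it by default), and the nRMSE between
measured and predicted curves is compared against those limits to yield a
Green / Yellow / Red label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .cohort_io import StanceCurve, SubjectRecord
from .exceptions import ConfigError, DegenerateTraceError

logger = logging.getLogger(__name__)

GREEN = "Green"
YELLOW = "Yellow"
RED = "Red"
#: canonical class order, also the tie-break order in the classifier
LABEL_ORDER = (GREEN, YELLOW, RED)

DEFAULT_LKL_FRACTION = 0.10
DEFAULT_UKL_FRACTION = 0.20


def _values(curve) -> np.ndarray:
    if isinstance(curve, StanceCurve):
        return curve.values
    return np.asarray(curve, dtype=float)


def standardized_peak(moment) -> float:
    """Standardized peak of a moment trace: (max - mean) / sample sd.

    Dimensionless, strictly positive for any non-constant curve, and
    invariant under constant shifts and positive rescaling.

    Raises
    ------
    DegenerateTraceError
        If the trace is constant (sample standard deviation is zero).
    """
    v = _values(moment)
    sd = float(np.std(v, ddof=1))
    if not sd > 0.0:
        raise DegenerateTraceError(
            "constant moment trace: standardized peak undefined (sd = 0)"
        )
    return float((np.max(v) - np.mean(v)) / sd)


@dataclass(frozen=True)
class ThresholdPair:
    """Lower / upper kinetic limits derived from a standardized peak."""

    max_mom_star: float
    lkl: float
    ukl: float
    lkl_fraction: float = DEFAULT_LKL_FRACTION
    ukl_fraction: float = DEFAULT_UKL_FRACTION


def kinetic_limits(
    moment,
    lkl_fraction: float = DEFAULT_LKL_FRACTION,
    ukl_fraction: float = DEFAULT_UKL_FRACTION,
) -> ThresholdPair:
    """Compute the acceptance band (LKL, UKL) of a measured moment trace."""
    if not (0.0 < lkl_fraction < ukl_fraction):
        raise ConfigError(
            f"need 0 < lkl_fraction < ukl_fraction, got "
            f"({lkl_fraction}, {ukl_fraction})"
        )
    star = standardized_peak(moment)
    return ThresholdPair(
        max_mom_star=star,
        lkl=lkl_fraction * star,
        ukl=ukl_fraction * star,
        lkl_fraction=lkl_fraction,
        ukl_fraction=ukl_fraction,
    )


def nrmse(
    measured,
    predicted,
    *,
    normalization: Literal["measured", "combined"] = "measured",
) -> float:
    """RMSE between curves normalized by the peak-to-peak amplitude.

    By default the normalizing range is that of the *measured* curve, so
    prediction error cannot move its own denominator; ``combined`` uses
    the range of both curves pooled.
    """
    m = _values(measured)
    p = _values(predicted)
    if m.shape != p.shape:
        raise ValueError(
            f"curve length mismatch: {m.shape} vs {p.shape}"
        )
    if normalization == "measured":
        p2p = float(np.max(m) - np.min(m))
    elif normalization == "combined":
        both = np.concatenate([m, p])
        p2p = float(np.max(both) - np.min(both))
    else:
        raise ConfigError(f"unknown normalization {normalization!r}")
    if not p2p > 0.0:
        raise DegenerateTraceError(
            "flat measured trace: peak-to-peak is zero, nRMSE undefined"
        )
    rmse = float(np.sqrt(np.mean((m - p) ** 2)))
    return rmse / p2p


def assign_label(nrmse_value: float, thresholds: ThresholdPair) -> str:
    """Map an nRMSE value to Green (acceptable, strictly below LKL),
    Red (unacceptable, strictly above UKL) or Yellow (in between;
    boundary ties are Yellow)."""
    if nrmse_value < 0:
        raise ValueError(f"nRMSE must be >= 0, got {nrmse_value}")
    if nrmse_value < thresholds.lkl:
        return GREEN
    if nrmse_value > thresholds.ukl:
        return RED
    return YELLOW


@dataclass(frozen=True)
class MomentLabelResult:
    subject_id: str
    side: str
    joint: str
    nrmse: float
    thresholds: ThresholdPair
    label: str


@dataclass
class LabelSummary:
    """Per-label population counts, percentages and nRMSE statistics for
    one joint (one block of the label-population table)."""

    joint: str
    total: int
    excluded: int
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    nrmse_mean: dict[str, float] = field(default_factory=dict)
    nrmse_sd: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in LABEL_ORDER:
            rows.append(
                {
                    "joint": self.joint,
                    "label": label,
                    "population": self.counts.get(label, 0),
                    "percentage": self.percentages.get(label, 0.0),
                    "nrmse_mean": self.nrmse_mean.get(label, np.nan),
                    "nrmse_sd": self.nrmse_sd.get(label, np.nan),
                }
            )
        return pd.DataFrame(rows)


def label_cohort(
    records: Iterable[SubjectRecord],
    joint: str,
    *,
    lkl_fraction: float = DEFAULT_LKL_FRACTION,
    ukl_fraction: float = DEFAULT_UKL_FRACTION,
    threshold_mode: Literal["per_record", "cohort_peaks"] = "per_record",
    normalization: Literal["measured", "combined"] = "measured",
) -> tuple[list[MomentLabelResult], LabelSummary]:
    """Label every record's predicted moment for one joint.

    ``threshold_mode='per_record'`` (default) standardizes the peak within
    each record's own measured trace; ``'cohort_peaks'`` standardizes each
    record's peak against the cohort distribution of peaks instead.
    Records with degenerate traces are excluded from the summary and
    counted (with a logged warning), not imputed.
    """
    if not (0.0 < lkl_fraction < ukl_fraction):
        raise ConfigError(
            f"need 0 < lkl_fraction < ukl_fraction, got "
            f"({lkl_fraction}, {ukl_fraction})"
        )
    records = list(records)
    for rec in records:
        if joint not in rec.measured_moments or joint not in rec.predicted_moments:
            raise ConfigError(
                f"subject {rec.subject_id!r} side {rec.side!r} has no "
                f"{joint!r} moment curves"
            )

    stars: list[float | None] = []
    if threshold_mode == "per_record":
        for rec in records:
            try:
                stars.append(standardized_peak(rec.measured_moments[joint]))
            except DegenerateTraceError:
                stars.append(None)
    elif threshold_mode == "cohort_peaks":
        peaks = np.array(
            [float(np.max(rec.measured_moments[joint].values)) for rec in records]
        )
        sd = float(np.std(peaks, ddof=1)) if peaks.size > 1 else 0.0
        if not sd > 0.0:
            raise DegenerateTraceError(
                "cohort peak distribution is degenerate (sd = 0)"
            )
        mean = float(np.mean(peaks))
        stars = [float((p - mean) / sd) for p in peaks]
    else:
        raise ConfigError(f"unknown threshold_mode {threshold_mode!r}")

    results: list[MomentLabelResult] = []
    excluded = 0
    for rec, star in zip(records, stars):
        if star is None or not star > 0.0:
            excluded += 1
            continue
        try:
            err = nrmse(
                rec.measured_moments[joint],
                rec.predicted_moments[joint],
                normalization=normalization,
            )
        except DegenerateTraceError:
            excluded += 1
            continue
        thr = ThresholdPair(
            max_mom_star=star,
            lkl=lkl_fraction * star,
            ukl=ukl_fraction * star,
            lkl_fraction=lkl_fraction,
            ukl_fraction=ukl_fraction,
        )
        results.append(
            MomentLabelResult(
                subject_id=rec.subject_id,
                side=rec.side,
                joint=joint,
                nrmse=err,
                thresholds=thr,
                label=assign_label(err, thr),
            )
        )
    if excluded:
        logger.warning(
            "%d of %d records excluded from %s-moment labeling "
            "(degenerate or non-positive standardized peak)",
            excluded,
            len(records),
            joint,
        )

    summary = LabelSummary(joint=joint, total=len(results), excluded=excluded)
    included = len(results)
    for label in LABEL_ORDER:
        vals = np.array([r.nrmse for r in results if r.label == label])
        summary.counts[label] = int(vals.size)
        summary.percentages[label] = (
            100.0 * vals.size / included if included else 0.0
        )
        summary.nrmse_mean[label] = float(np.mean(vals)) if vals.size else np.nan
        summary.nrmse_sd[label] = (
            float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        )
    return results, summary


def labels_to_frame(results: Sequence[MomentLabelResult]) -> pd.DataFrame:
    """Per-record label table (subject, side, joint, nrmse, band, label)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "side": r.side,
                "joint": r.joint,
                "nrmse": r.nrmse,
                "max_mom_star": r.thresholds.max_mom_star,
                "lkl": r.thresholds.lkl,
                "ukl": r.thresholds.ukl,
                "label": r.label,
            }
            for r in results
        ]
    )
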