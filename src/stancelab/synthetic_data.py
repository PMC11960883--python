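"""Synthetic cohort generator.

Produces stance-phase records with the statistical structure the analysis
assumes: crouch-like sagittal kinematics driven by a severity parameter in
[0, 1] (knee mean shifted up to +15 deg, hip ROM reduced up to 10 deg,
ankle peak dorsiflexion reduced up to 10 deg at severity 1), physiological
moment templates per joint, and predicted moments whose injected smooth
error hits a per-record nRMSE target drawn from a tier (Green / Yellow /
Red) whose odds shift toward Red as severity rises.

All randomness flows from one seed: a ``SeedSequence`` is spawned into one
child stream per subject, so cohorts are bit-reproducible and records are
independent of cohort size ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    CANONICAL_N,
    DEGREES,
    JOINTS,
    MOMENT_STEMS,
    NM_PER_KG,
    ReferenceProfile,
    SAGITTAL_VARIABLES,
    StanceCurve,
    SubjectRecord,
)
from .exceptions import ConfigError, DegenerateTraceError
from .kinetics_labeling import (
    GREEN,
    LABEL_ORDER,
    RED,
    YELLOW,
    assign_label,
    kinetic_limits,
    nrmse,
)

_T = np.linspace(0.0, 1.0, CANONICAL_N)

#: default absolute nRMSE bands per tier (used in "absolute" tier mode)
DEFAULT_TIER_BANDS: dict[str, tuple[float, float]] = {
    GREEN: (0.05, 0.12),
    YELLOW: (0.15, 0.25),
    RED: (0.30, 0.50),
}

#: default per-joint base tier probabilities (Green, Yellow, Red)
DEFAULT_TIER_PROBABILITIES: dict[str, tuple[float, float, float]] = {
    "hip": (0.84, 0.15, 0.01),
    "knee": (0.60, 0.33, 0.07),
    "ankle": (0.50, 0.40, 0.10),
}

# relative-mode target draw, as a fraction of the record's own band
_REL_GREEN = (0.30, 0.90)   # x LKL
_REL_YELLOW = (0.10, 0.90)  # LKL + x (UKL - LKL)
_REL_RED = (0.10, 0.80)     # UKL x (1 + x)


@dataclass
class SyntheticConfig:
    n_subjects: int = 100
    seed: int = 0
    severity_distribution: str | tuple = "uniform"  # or ("beta", a, b)
    tier_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TIER_BANDS)
    )
    tier_probabilities_base: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TIER_PROBABILITIES)
    )
    severity_coupling: float = 1.0
    kinematic_noise_sd: float = 1.5  # degrees
    moment_shape_noise_sd: float = 0.03  # Nm/kg
    moment_amplitude_jitter: float = 0.08
    tier_mode: str = "relative"  # or "absolute"
    joints: tuple[str, ...] = JOINTS
    paired_sides: bool = False

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_subjects < 1:
            problems.append(f"n_subjects must be >= 1, got {self.n_subjects}")
        dist = self.severity_distribution
        if isinstance(dist, str):
            if dist != "uniform":
                problems.append(f"unknown severity_distribution {dist!r}")
        elif not (
            isinstance(dist, (tuple, list))
            and len(dist) == 3
            and dist[0] == "beta"
            and float(dist[1]) > 0
            and float(dist[2]) > 0
        ):
            problems.append(f"unknown severity_distribution {dist!r}")
        prev_hi = -np.inf
        for tier in LABEL_ORDER:
            lo, hi = self.tier_targets.get(tier, (np.nan, np.nan))
            if not (0 <= lo < hi):
                problems.append(f"tier band for {tier} must satisfy 0 <= lo < hi")
            elif lo < prev_hi:
                problems.append(f"tier band for {tier} overlaps the previous band")
            else:
                prev_hi = hi
        for joint in self.joints:
            if joint not in JOINTS:
                problems.append(f"unknown joint {joint!r}")
                continue
            probs = self.tier_probabilities_base.get(joint)
            if probs is None:
                problems.append(f"no base tier probabilities for joint {joint!r}")
                continue
            arr = np.asarray(probs, dtype=float)
            if arr.size != 3 or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                problems.append(
                    f"tier probabilities for {joint!r} must be 3 values in "
                    f"[0, 1] summing to 1"
                )
        if self.severity_coupling < 0:
            problems.append("severity_coupling must be >= 0")
        if self.kinematic_noise_sd < 0:
            problems.append("kinematic_noise_sd must be >= 0")
        if self.tier_mode not in ("relative", "absolute"):
            problems.append(f"unknown tier_mode {self.tier_mode!r}")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "severity_distribution": list(self.severity_distribution)
            if not isinstance(self.severity_distribution, str)
            else self.severity_distribution,
            "tier_targets": {k: list(v) for k, v in self.tier_targets.items()},
            "tier_probabilities_base": {
                k: list(v) for k, v in self.tier_probabilities_base.items()
            },
            "severity_coupling": self.severity_coupling,
            "kinematic_noise_sd": self.kinematic_noise_sd,
            "moment_shape_noise_sd": self.moment_shape_noise_sd,
            "moment_amplitude_jitter": self.moment_amplitude_jitter,
            "tier_mode": self.tier_mode,
            "joints": list(self.joints),
            "paired_sides": self.paired_sides,
        }


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------

def kinematic_templates(severity: float) -> dict[str, np.ndarray]:
    """Noise-free sagittal templates (degrees) at a given severity."""
    t = _T
    return {
        "PelvicTilt": 16.0 + 2.5 * np.sin(2 * np.pi * t) + 1.5 * np.cos(2 * np.pi * t),
        # hip flexes ~38 deg at strike, extends through stance; amplitude
        # shrinks with severity so ROM drops by 10 deg at severity 1
        "HipFlx": 18.0 + (20.0 - 5.0 * severity) * np.cos(np.pi * t),
        # crouch: knee mean rises by exactly +15 deg at severity 1
        "KneeFlx": (21.0 + 15.0 * severity)
        - 9.0 * np.cos(2 * np.pi * t)
        + 4.0 * np.sin(2 * np.pi * t),
        # peak dorsiflexion falls by ~10 deg at severity 1
        "AnkleDorsi": 5.0 + (9.0 - 10.0 * severity) * np.sin(np.pi * t)
        - 1.0 * np.cos(2 * np.pi * t),
    }


def moment_templates() -> dict[str, np.ndarray]:
    """Noise-free joint moment templates (Nm/kg)."""
    t = _T
    return {
        # extensor-to-flexor biphasic
        "hip": 0.85 * np.cos(np.pi * t) - 0.15 + 0.10 * np.sin(2 * np.pi * t),
        # flexion-extension wave
        "knee": 0.35 * np.sin(2 * np.pi * t) + 0.25 * np.cos(np.pi * t) + 0.05,
        # monotone rise to a late-stance plantarflexor peak ~1.4 Nm/kg
        "ankle": 1.4 * np.sin(np.pi * t**1.5),
    }


def _smooth_noise(rng: np.random.Generator, sd: float, n_harmonics: int = 4) -> np.ndarray:
    """Low-order random Fourier series over stance, scaled by ``sd``."""
    if sd == 0.0:
        return np.zeros(CANONICAL_N)
    out = rng.normal(0.0, 0.5) * np.ones(CANONICAL_N)
    for h in range(1, n_harmonics + 1):
        a, b = rng.normal(0.0, 1.0 / h, size=2)
        out = out + a * np.cos(2 * np.pi * h * _T) + b * np.sin(2 * np.pi * h * _T)
    return sd * out


def generate_kinematics(
    severity: float,
    rng: np.random.Generator,
    noise_sd: float = 1.5,
) -> dict[str, StanceCurve]:
    """Sagittal kinematic curves at a severity, plus smooth subject noise.

    At severity 0 with ``noise_sd=0`` this returns the templates exactly.
    """
    if not (0.0 <= severity <= 1.0):
        raise ConfigError(f"severity must be in [0, 1], got {severity}")
    curves = {}
    for var, template in kinematic_templates(severity).items():
        values = template + _smooth_noise(rng, noise_sd)
        curves[var] = StanceCurve(values, units=DEGREES, variable_name=var)
    return curves


def generate_moments(
    severity: float,
    rng: np.random.Generator,
    amplitude_jitter: float = 0.08,
    shape_noise_sd: float = 0.03,
    joints: Sequence[str] = JOINTS,
) -> dict[str, StanceCurve]:
    """Measured joint moment curves: templates with subject-level amplitude
    jitter (clipped to +/-25%) and a small smooth shape perturbation so
    standardized peaks vary across subjects.  Non-constant by construction.
    """
    if not (0.0 <= severity <= 1.0):
        raise ConfigError(f"severity must be in [0, 1], got {severity}")
    templates = moment_templates()
    out = {}
    for joint in joints:
        gain = 1.0
        if amplitude_jitter > 0:
            gain = 1.0 + float(
                np.clip(rng.normal(0.0, amplitude_jitter), -0.25, 0.25)
            )
        values = gain * templates[joint] + _smooth_noise(rng, shape_noise_sd)
        out[joint] = StanceCurve(
            values, units=NM_PER_KG, variable_name=f"{MOMENT_STEMS[joint]}_measured"
        )
    return out


def inject_prediction_error(
    measured: StanceCurve,
    target_nrmse: float,
    rng: np.random.Generator,
    subphase_weights: Sequence[float] | None = None,
) -> StanceCurve:
    """Return a predicted curve whose nRMSE against ``measured`` equals
    ``target_nrmse`` exactly (to floating-point rescaling error).

    The error is a low-order random Fourier series, optionally reweighted
    per stance subphase, then rescaled so its RMS equals
    ``target * peak-to-peak(measured)``.
    """
    if target_nrmse < 0:
        raise ConfigError(f"target_nrmse must be >= 0, got {target_nrmse}")
    m = measured.values
    p2p = float(np.max(m) - np.min(m))
    if not p2p > 0.0:
        raise DegenerateTraceError("cannot inject error into a flat trace")
    name = (measured.variable_name or "moment").replace("_measured", "") + "_predicted"
    if target_nrmse == 0.0:
        return StanceCurve(m.copy(), units=measured.units, variable_name=name)
    for _ in range(100):
        err = _smooth_noise(rng, 1.0)
        if subphase_weights is not None:
            w = np.asarray(subphase_weights, dtype=float)
            if m.size % w.size != 0:
                raise ConfigError(
                    f"{m.size} samples not divisible by {w.size} subphase weights"
                )
            err = err * np.repeat(w, m.size // w.size)
        rms = float(np.sqrt(np.mean(err**2)))
        if rms > 0:
            break
    else:  # pragma: no cover - probability zero
        raise RuntimeError("could not draw a non-zero error waveform")
    err *= target_nrmse * p2p / rms
    return StanceCurve(m + err, units=measured.units, variable_name=name)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _draw_severity(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    dist = cfg.severity_distribution
    if dist == "uniform":
        return float(rng.uniform(0.0, 1.0))
    return float(rng.beta(float(dist[1]), float(dist[2])))


def _tier_probabilities(
    base: Sequence[float], severity: float, coupling: float
) -> np.ndarray:
    """Shift tier odds toward Red as severity rises; severity 0.5 is the
    pivot so that, under a uniform severity, marginal frequencies stay
    close to the base probabilities."""
    w = np.asarray(base, dtype=float) * np.exp(
        coupling * (severity - 0.5) * np.arange(3)
    )
    return w / w.sum()


def _draw_target(
    tier: str,
    thresholds,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Draw the nRMSE target for a tier; returns (target, flagged).

    Relative mode places the target strictly inside the record's own band,
    so the labeling stage recovers the tier exactly.  Absolute mode draws
    from the configured band and flags records whose personal thresholds
    make that band land in a different label.
    """
    if cfg.tier_mode == "relative":
        if tier == GREEN:
            target = rng.uniform(*_REL_GREEN) * thresholds.lkl
        elif tier == YELLOW:
            target = thresholds.lkl + rng.uniform(*_REL_YELLOW) * (
                thresholds.ukl - thresholds.lkl
            )
        else:
            target = thresholds.ukl * (1.0 + rng.uniform(*_REL_RED))
        return float(target), False
    lo, hi = cfg.tier_targets[tier]
    target = float(rng.uniform(lo, hi))
    flagged = assign_label(target, thresholds) != tier
    return target, flagged


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SubjectRecord], pd.DataFrame, ReferenceProfile]:
    """Generate a cohort, its ground truth, and the GPS reference.

    Returns records (one side per subject unless ``paired_sides``), a
    ground-truth table with columns ``subject_id, side, joint, severity,
    tier, target_nrmse, flagged``, and the severity-0 noise-free
    reference profile.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    records: list[SubjectRecord] = []
    truth_rows: list[dict] = []
    sides = ("left", "right") if config.paired_sides else ("left",)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = f"S{i:05d}"
        severity = _draw_severity(config, rng)
        for side in sides:
            kinematics = generate_kinematics(severity, rng, config.kinematic_noise_sd)
            measured = generate_moments(
                severity,
                rng,
                config.moment_amplitude_jitter,
                config.moment_shape_noise_sd,
                config.joints,
            )
            predicted: dict[str, StanceCurve] = {}
            for joint in config.joints:
                thr = kinetic_limits(measured[joint])
                probs = _tier_probabilities(
                    config.tier_probabilities_base[joint],
                    severity,
                    config.severity_coupling,
                )
                tier = LABEL_ORDER[int(rng.choice(3, p=probs))]
                target, flagged = _draw_target(tier, thr, config, rng)
                predicted[joint] = inject_prediction_error(
                    measured[joint], target, rng
                )
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "side": side,
                        "joint": joint,
                        "severity": severity,
                        "tier": tier,
                        "target_nrmse": target,
                        "flagged": flagged,
                    }
                )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    side=side,
                    kinematics=kinematics,
                    measured_moments=measured,
                    predicted_moments=predicted,
                    severity=severity,
                )
            )
    reference = ReferenceProfile(
        mean_curves={
            var: StanceCurve(vals, units=DEGREES, variable_name=var)
            for var, vals in kinematic_templates(0.0).items()
        },
        description="severity-0 noise-free kinematic templates",
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "subject_id",
            "side",
            "joint",
            "severity",
            "tier",
            "target_nrmse",
            "flagged",
        ],
    )
    return records, truth, reference
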