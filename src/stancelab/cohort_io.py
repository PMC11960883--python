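"""Cohort file I/O, validation, and stance-curve resampling.

Interchange format is a long-form CSV with columns

    subject_id, side, variable, sample_index, value

where ``sample_index`` runs 0..59 over the stance phase (foot strike to
foot off inclusive).  Kinematic variables use plain names (``PelvicTilt``,
``HipFlx``, ``KneeFlx``, ``AnkleDorsi``, ...); moment traces are encoded as
``<Joint>Mom_measured`` / ``<Joint>Mom_predicted`` with joint in
{Hip, Knee, Ankle}.  An optional sidecar ``<stem>.meta.csv`` carries
per-record metadata (``severity``, ``group``).  A JSON mirror of the same
schema is provided.  Left and right sides are independent records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError

#: canonical number of stance samples (foot strike .. foot off, inclusive)
CANONICAL_N = 60

SIDES = ("left", "right")
JOINTS = ("hip", "knee", "ankle")

#: the four sagittal kinematic variables every record must carry
SAGITTAL_VARIABLES = ("PelvicTilt", "HipFlx", "KneeFlx", "AnkleDorsi")

#: CSV variable-name stem per joint for moment traces
MOMENT_STEMS = {"hip": "HipMom", "knee": "KneeMom", "ankle": "AnkleMom"}
_STEM_TO_JOINT = {v: k for k, v in MOMENT_STEMS.items()}

DEGREES = "degrees"
NM_PER_KG = "Nm/kg"

_COHORT_COLUMNS = ["subject_id", "side", "variable", "sample_index", "value"]


@dataclass(frozen=True)
class StanceCurve:
    """A time-normalized scalar gait series over the stance phase.

    Canonical curves hold exactly :data:`CANONICAL_N` samples; intermediate
    (pre-resampling) curves may be any length >= 2.  Values must be finite.
    """

    values: np.ndarray
    units: str
    variable_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise CohortValidationError(
                f"curve {self.variable_name!r} needs a 1-D sequence of >= 2 "
                f"samples, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise CohortValidationError(
                f"curve {self.variable_name!r} has a non-finite sample at "
                f"index {bad}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def is_canonical(self) -> bool:
        return self.n_samples == CANONICAL_N

    def __array__(self, dtype=None, copy=None):  # numpy interop
        return np.asarray(self.values, dtype=dtype)


@dataclass
class SubjectRecord:
    """Kinematics plus measured/predicted moment curves for one side of one
    subject."""

    subject_id: str
    side: str
    kinematics: dict[str, StanceCurve]
    measured_moments: dict[str, StanceCurve]
    predicted_moments: dict[str, StanceCurve]
    severity: float | None = None
    group: str | None = None

    def validate(self, require_sagittal: bool = True) -> None:
        if self.side not in SIDES:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: side must be one of {SIDES}, "
                f"got {self.side!r}"
            )
        if require_sagittal:
            for var in SAGITTAL_VARIABLES:
                if var not in self.kinematics:
                    raise CohortValidationError(
                        f"subject {self.subject_id!r} side {self.side!r}: "
                        f"missing required kinematic variable {var!r}"
                    )
        if set(self.measured_moments) != set(self.predicted_moments):
            raise CohortValidationError(
                f"subject {self.subject_id!r} side {self.side!r}: measured "
                f"and predicted moment joints differ "
                f"({sorted(self.measured_moments)} vs "
                f"{sorted(self.predicted_moments)})"
            )
        for name, curve in self.iter_curves():
            if not curve.is_canonical:
                raise CohortValidationError(
                    f"subject {self.subject_id!r} side {self.side!r}: curve "
                    f"{name!r} has {curve.n_samples} samples, expected "
                    f"{CANONICAL_N}"
                )

    def iter_curves(self) -> Iterable[tuple[str, StanceCurve]]:
        """Yield (csv-variable-name, curve) in the canonical write order."""
        for var in sorted(self.kinematics, key=_kinematic_sort_key):
            yield var, self.kinematics[var]
        for joint in JOINTS:
            if joint in self.measured_moments:
                yield f"{MOMENT_STEMS[joint]}_measured", self.measured_moments[joint]
        for joint in JOINTS:
            if joint in self.predicted_moments:
                yield f"{MOMENT_STEMS[joint]}_predicted", self.predicted_moments[joint]


@dataclass
class ReferenceProfile:
    """Typically-developed mean kinematic curves used as the GPS reference."""

    mean_curves: dict[str, StanceCurve]
    description: str = ""

    def require(self, variables: Sequence[str]) -> None:
        for var in variables:
            if var not in self.mean_curves:
                raise CohortValidationError(
                    f"reference profile is missing variable {var!r}"
                )


def _kinematic_sort_key(var: str):
    try:
        return (0, SAGITTAL_VARIABLES.index(var), var)
    except ValueError:
        return (1, 0, var)


def resample_stance(
    raw_values: Sequence[float],
    n_points: int = CANONICAL_N,
    *,
    units: str = DEGREES,
    variable_name: str = "",
) -> StanceCurve:
    """Linearly resample a raw stance series onto ``n_points`` uniformly
    spaced parameters from the first to the last sample.

    Endpoints are preserved exactly and an input already at the target
    length is returned unchanged.
    """
    arr = np.asarray(raw_values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise CohortValidationError(
            f"resampling needs >= 2 samples, got {arr.size}"
        )
    if n_points < 2:
        raise CohortValidationError(f"n_points must be >= 2, got {n_points}")
    if arr.size == n_points:
        out = arr.copy()
    else:
        x_old = np.linspace(0.0, 1.0, arr.size)
        x_new = np.linspace(0.0, 1.0, n_points)
        out = np.interp(x_new, x_old, arr)
        out[0] = arr[0]
        out[-1] = arr[-1]
    return StanceCurve(out, units=units, variable_name=variable_name)


# ---------------------------------------------------------------------------
# long-form CSV cohort interchange
# ---------------------------------------------------------------------------

def _meta_path_for(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.csv")


def _classify_variable(var: str) -> tuple[str, str, str]:
    """Map a CSV variable name to (kind, key, units).

    kind is 'kinematic', 'measured' or 'predicted'; key is the kinematic
    variable name or the joint name.
    """
    for suffix, kind in (("_measured", "measured"), ("_predicted", "predicted")):
        if var.endswith(suffix):
            stem = var[: -len(suffix)]
            if stem in _STEM_TO_JOINT:
                return kind, _STEM_TO_JOINT[stem], NM_PER_KG
    return "kinematic", var, DEGREES


def read_cohort(
    path: str | Path,
    *,
    require_sagittal: bool = True,
    meta_path: str | Path | None = None,
) -> list[SubjectRecord]:
    """Read a long-form cohort CSV into a sorted list of
    :class:`SubjectRecord` (one per subject_id x side)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "side": str, "variable": str},
        float_precision="round_trip",
    )
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing required columns {missing}"
        )
    values = df["value"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise CohortValidationError(
            f"{path}: non-finite value at row {int(bad[0])}"
        )

    meta: dict[tuple[str, str], dict] = {}
    mpath = Path(meta_path) if meta_path is not None else _meta_path_for(path)
    if mpath.exists():
        mdf = pd.read_csv(
            mpath,
            dtype={"subject_id": str, "side": str},
            float_precision="round_trip",
        )
        for row in mdf.itertuples(index=False):
            entry = {}
            sev = getattr(row, "severity", None)
            if sev is not None and np.isfinite(float(sev)):
                entry["severity"] = float(sev)
            grp = getattr(row, "group", None)
            if isinstance(grp, str):
                entry["group"] = grp
            meta[(row.subject_id, row.side)] = entry

    records: list[SubjectRecord] = []
    for (sid, side), grp in df.groupby(["subject_id", "side"], sort=True):
        kinematics: dict[str, StanceCurve] = {}
        measured: dict[str, StanceCurve] = {}
        predicted: dict[str, StanceCurve] = {}
        for var, sub in grp.groupby("variable", sort=True):
            sub = sub.sort_values("sample_index")
            idx = sub["sample_index"].to_numpy(dtype=int)
            if idx.size != CANONICAL_N or not np.array_equal(
                idx, np.arange(CANONICAL_N)
            ):
                raise CohortValidationError(
                    f"subject {sid!r} side {side!r} variable {var!r}: "
                    f"sample_index must cover 0..{CANONICAL_N - 1} exactly"
                )
            kind, key, units = _classify_variable(var)
            curve = StanceCurve(
                sub["value"].to_numpy(dtype=float), units=units, variable_name=var
            )
            if kind == "kinematic":
                kinematics[key] = curve
            elif kind == "measured":
                measured[key] = curve
            else:
                predicted[key] = curve
        extra = meta.get((sid, side), {})
        rec = SubjectRecord(
            subject_id=sid,
            side=side,
            kinematics=kinematics,
            measured_moments=measured,
            predicted_moments=predicted,
            severity=extra.get("severity"),
            group=extra.get("group"),
        )
        rec.validate(require_sagittal=require_sagittal)
        records.append(rec)
    return records


def write_cohort(
    records: Iterable[SubjectRecord],
    path: str | Path,
    *,
    meta_path: str | Path | None = None,
) -> None:
    """Write records to the long-form CSV (and a metadata sidecar when any
    record carries severity/group).  Deterministic: records are sorted by
    (subject_id, side) and variables follow the canonical order, so
    write -> read -> write is byte-identical."""
    path = Path(path)
    records = sorted(records, key=lambda r: (r.subject_id, r.side))
    for rec in records:
        rec.validate(require_sagittal=False)

    rows_sid: list[str] = []
    rows_side: list[str] = []
    rows_var: list[str] = []
    chunks: list[np.ndarray] = []
    for rec in records:
        for var, curve in rec.iter_curves():
            rows_sid.extend([rec.subject_id] * CANONICAL_N)
            rows_side.extend([rec.side] * CANONICAL_N)
            rows_var.extend([var] * CANONICAL_N)
            chunks.append(curve.values)
    df = pd.DataFrame(
        {
            "subject_id": rows_sid,
            "side": rows_side,
            "variable": rows_var,
            "sample_index": np.tile(np.arange(CANONICAL_N), len(chunks)),
            "value": np.concatenate(chunks) if chunks else np.array([], dtype=float),
        }
    )
    df.to_csv(path, index=False)

    has_meta = any(r.severity is not None or r.group is not None for r in records)
    mpath = Path(meta_path) if meta_path is not None else _meta_path_for(path)
    if has_meta:
        mrows = []
        for rec in records:
            mrows.append(
                {
                    "subject_id": rec.subject_id,
                    "side": rec.side,
                    "severity": rec.severity if rec.severity is not None else np.nan,
                    "group": rec.group if rec.group is not None else "",
                }
            )
        pd.DataFrame(mrows).to_csv(mpath, index=False)


# ---------------------------------------------------------------------------
# JSON mirror
# ---------------------------------------------------------------------------

def write_cohort_json(records: Iterable[SubjectRecord], path: str | Path) -> None:
    records = sorted(records, key=lambda r: (r.subject_id, r.side))
    payload = []
    for rec in records:
        rec.validate(require_sagittal=False)
        payload.append(
            {
                "subject_id": rec.subject_id,
                "side": rec.side,
                "severity": rec.severity,
                "group": rec.group,
                "kinematics": {k: list(v.values) for k, v in rec.kinematics.items()},
                "measured_moments": {
                    k: list(v.values) for k, v in rec.measured_moments.items()
                },
                "predicted_moments": {
                    k: list(v.values) for k, v in rec.predicted_moments.items()
                },
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_cohort_json(path: str | Path, *, require_sagittal: bool = True) -> list[SubjectRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for entry in payload:
        rec = SubjectRecord(
            subject_id=entry["subject_id"],
            side=entry["side"],
            kinematics={
                k: StanceCurve(v, units=DEGREES, variable_name=k)
                for k, v in entry["kinematics"].items()
            },
            measured_moments={
                k: StanceCurve(v, units=NM_PER_KG, variable_name=f"{MOMENT_STEMS[k]}_measured")
                for k, v in entry["measured_moments"].items()
            },
            predicted_moments={
                k: StanceCurve(v, units=NM_PER_KG, variable_name=f"{MOMENT_STEMS[k]}_predicted")
                for k, v in entry["predicted_moments"].items()
            },
            severity=entry.get("severity"),
            group=entry.get("group"),
        )
        rec.validate(require_sagittal=require_sagittal)
        records.append(rec)
    return sorted(records, key=lambda r: (r.subject_id, r.side))


# ---------------------------------------------------------------------------
# reference-profile CSV (variable, sample_index, mean_value)
# ---------------------------------------------------------------------------

def write_reference(profile: ReferenceProfile, path: str | Path) -> None:
    rows_var, chunks = [], []
    for var in sorted(profile.mean_curves, key=_kinematic_sort_key):
        rows_var.extend([var] * CANONICAL_N)
        chunks.append(profile.mean_curves[var].values)
    df = pd.DataFrame(
        {
            "variable": rows_var,
            "sample_index": np.tile(np.arange(CANONICAL_N), len(chunks)),
            "mean_value": np.concatenate(chunks) if chunks else np.array([]),
        }
    )
    df.to_csv(path, index=False)


def read_reference(path: str | Path, description: str = "") -> ReferenceProfile:
    df = pd.read_csv(path, dtype={"variable": str}, float_precision="round_trip")
    curves: dict[str, StanceCurve] = {}
    for var, sub in df.groupby("variable", sort=True):
        sub = sub.sort_values("sample_index")
        curves[var] = StanceCurve(
            sub["mean_value"].to_numpy(dtype=float), units=DEGREES, variable_name=var
        )
    return ReferenceProfile(mean_curves=curves, description=description)
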