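import numpy as np
import pytest

from stancelab import (
    CANONICAL_N,
    ReferenceProfile,
    StanceCurve,
    SubjectRecord,
    SyntheticConfig,
    generate_cohort,
)
from stancelab.cohort_io import DEGREES, NM_PER_KG
from stancelab.synthetic_data import kinematic_templates, moment_templates


def make_record(
    subject_id="S0",
    side="left",
    severity=0.0,
    kinematic_offsets=None,
    moment_scale=1.0,
    prediction_offset=0.0,
):
    """Deterministic record built from the noise-free templates; predicted
    moments are the measured ones plus a constant offset."""
    kin = {}
    for var, vals in kinematic_templates(severity).items():
        shift = (kinematic_offsets or {}).get(var, 0.0)
        kin[var] = StanceCurve(vals + shift, units=DEGREES, variable_name=var)
    measured, predicted = {}, {}
    for joint, vals in moment_templates().items():
        measured[joint] = StanceCurve(
            moment_scale * vals, units=NM_PER_KG, variable_name=joint
        )
        predicted[joint] = StanceCurve(
            moment_scale * vals + prediction_offset,
            units=NM_PER_KG,
            variable_name=joint,
        )
    return SubjectRecord(
        subject_id=subject_id,
        side=side,
        kinematics=kin,
        measured_moments=measured,
        predicted_moments=predicted,
    )


@pytest.fixture
def template_record():
    return make_record()


@pytest.fixture
def template_reference():
    return ReferenceProfile(
        mean_curves={
            var: StanceCurve(vals, units=DEGREES, variable_name=var)
            for var, vals in kinematic_templates(0.0).items()
        },
        description="templates at severity 0",
    )


@pytest.fixture(scope="session")
def cohort300():
    """Mid-sized synthetic cohort shared across fast tests."""
    return generate_cohort(SyntheticConfig(n_subjects=300, seed=7))


@pytest.fixture(scope="session")
def cohort2000():
    """Large cohort used by the statistical acceptance checks."""
    return generate_cohort(SyntheticConfig(n_subjects=2000, seed=11))
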