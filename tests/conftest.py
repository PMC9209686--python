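import pytest

from sjstar.trial_data import PatientRecord, VisitMeasurements


def make_record(
    patient_id="p1",
    arm="treatment",
    baseline=None,
    followup=None,
    covariates=None,
    **instrument_pairs,
):
    """Build a PatientRecord from ``name=(baseline, followup)`` pairs."""
    base = dict(baseline or {})
    fu = dict(followup or {})
    for name, (b, f) in instrument_pairs.items():
        base[name] = b
        fu[name] = f
    return PatientRecord(
        patient_id=patient_id,
        arm=arm,
        baseline=VisitMeasurements(**base),
        followup=VisitMeasurements(**fu),
        covariates=covariates or {},
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_trial():
    from sjstar.simulate import SimConfig, positive_profile, simulate_trial

    return simulate_trial(
        SimConfig(trial_id="fixture", n=60, profile=positive_profile(), seed=7)
    )
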