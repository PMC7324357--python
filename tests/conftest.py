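import pytest

from deltap import synthetic
from deltap.scoring import Group, PatientRecord, Sex, TriState


@pytest.fixture(scope="session")
def table1_cohort():
    """The deterministic 87-patient cohort reproducing the published
    univariable-table marginal counts."""
    return synthetic.fixture_table1()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort (n=87, seed 11)."""
    return synthetic.generate(synthetic.GeneratorConfig(seed=11))


def make_record(pid="p1", group=Group.SCLC, sex=Sex.M, age=60.0, **kw):
    defaults = dict(
        bulbar_weakness=TriState.NO,
        erectile_dysfunction=TriState.NO,
        weight_loss_ge5pct=TriState.NO,
        smoking_at_onset=TriState.NO,
        karnofsky=80,
        followup_months=48.0,
    )
    defaults.update(kw)
    return PatientRecord(patient_id=pid, group=group, sex=sex,
                         age_years=age, **defaults)
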