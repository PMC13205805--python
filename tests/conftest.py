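import warnings

import pytest
from hypothesis import HealthCheck, settings

from picost import Cohort, GeneratorSpec, PatientRecord, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_cohort():
    """Calibrated 12-patient cohort at the study conditions (seed 1)."""
    return generate_cohort(seed=1)


@pytest.fixture
def flat_cohort():
    """Zero-dispersion calibrated cohort: every patient at the target means."""
    return generate_cohort(GeneratorSpec(sd_red_es=0.0, sd_red_pl=0.0, seed=7))


def make_cohort_from_reductions(red_es, red_pl, period=14.0, start=50.0,
                                design_r=20, depth="deep"):
    """Hand-build a cohort whose per-patient daily reductions are as given."""
    records = []
    for i, (re_, rp) in enumerate(zip(red_es, red_pl)):
        seq = "ES_first" if i % 2 == 0 else "placebo_first"
        r1, r2 = (re_, rp) if seq == "ES_first" else (rp, re_)
        s1 = max(start, period * max(r1, r1 + r2, 0.0))
        e1 = s1 - period * r1
        e2 = e1 - period * r2
        if seq == "ES_first":
            a_es, a_pl = (s1, e1), (e1, e2)
        else:
            a_pl, a_es = (s1, e1), (e1, e2)
        records.append(
            PatientRecord(
                patient_id=f"H{i:02d}",
                sequence=seq,
                area_es_start=a_es[0],
                area_es_end=a_es[1],
                area_pl_start=a_pl[0],
                area_pl_end=a_pl[1],
                design_r_total=design_r,
                depth=depth,
            )
        )
    return Cohort(records, period_length_days=period)


@pytest.fixture
def make_cohort():
    return make_cohort_from_reductions


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    """The default calibrated cohort legitimately produces >1% degenerate
    bootstrap resamples; keep that warning from cluttering test output."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*non-positive period-mean reduction.*"
        )
        yield
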