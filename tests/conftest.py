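import numpy as np
import pytest

from nflpower import Cohort, OnsetSite, PatientBaseline, Visit


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Two patients, hand-written linear trajectories, quarterly visits."""
    baselines = [
        PatientBaseline(
            patient_id="A",
            onset_site=OnsetSite.SPINAL,
            disease_duration_at_baseline=10.0,
            alsfrs_r_at_baseline=42,
            nfl_at_baseline=100.0,
        ),
        PatientBaseline(
            patient_id="B",
            onset_site=OnsetSite.BULBAR,
            disease_duration_at_baseline=12.0,
            alsfrs_r_at_baseline=36,
            nfl_at_baseline=150.0,
        ),
    ]
    visits = []
    for pid, base, slope in (("A", 42, -0.5), ("B", 36, -1.0)):
        for t in (0.0, 3.0, 6.0, 9.0):
            visits.append(
                Visit(
                    patient_id=pid,
                    months_since_baseline=t,
                    alsfrs_r=int(round(base + slope * t)),
                    nfl_pg_ml=100.0 if pid == "A" else 150.0,
                )
            )
    return Cohort(baselines=baselines, visits=visits, label="tiny")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210826)
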