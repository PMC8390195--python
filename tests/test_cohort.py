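"""Cohort ingestion, validation reporting, and round-trip fidelity."""

import textwrap

import pytest

from nflpower import (
    Cohort,
    CohortValidationError,
    ConfigurationError,
    OnsetSite,
    PatientBaseline,
    Visit,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from nflpower.synthetic import SyntheticConfig, generate_cohort


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


BASELINE_CSV = """\
patient_id,onset_site,disease_duration_at_baseline,alsfrs_r_at_baseline,nfl_at_baseline
A,spinal,10,42,100
B,bulbar,12,36,150
"""
VISITS_CSV = """\
patient_id,months_since_baseline,alsfrs_r
A,0,42
A,3,40
B,0,36
B,3,33
"""


def test_read_cohort_round_trip(tmp_path):
    """Two-table CSV input parses into 2 patients / 4 visits and survives a write/read cycle."""
    b = _write(tmp_path, "b.csv", BASELINE_CSV)
    v = _write(tmp_path, "v.csv", VISITS_CSV)
    cohort, rejected = read_cohort(b, v)
    assert rejected == []
    assert cohort.n_patients == 2
    assert len(cohort.visits) == 4

    write_cohort(cohort, tmp_path / "b2.csv", tmp_path / "v2.csv")
    again, rejected2 = read_cohort(tmp_path / "b2.csv", tmp_path / "v2.csv")
    assert rejected2 == []
    assert again.baselines == cohort.baselines
    assert again.visits == sorted(cohort.visits, key=lambda x: (x.patient_id, x.months_since_baseline))


def test_column_map_renames_headers(tmp_path):
    b = _write(
        tmp_path,
        "b.csv",
        """\
        id,site,dur,score,nfl
        A,Spinal,10,42,100
        """,
    )
    v = _write(
        tmp_path,
        "v.csv",
        """\
        id,month,frs
        A,0,42
        A,3,40
        """,
    )
    cmap = {
        "patient_id": "id",
        "onset_site": "site",
        "disease_duration_at_baseline": "dur",
        "alsfrs_r_at_baseline": "score",
        "nfl_at_baseline": "nfl",
        "months_since_baseline": "month",
        "alsfrs_r": "frs",
    }
    cohort, rejected = read_cohort(b, v, cmap)
    assert rejected == []
    assert cohort.baseline("A").onset_site is OnsetSite.SPINAL


def test_missing_required_column_is_configuration_error(tmp_path):
    b = _write(tmp_path, "b.csv", "patient_id,onset_site\nA,spinal\n")
    v = _write(tmp_path, "v.csv", VISITS_CSV)
    with pytest.raises(ConfigurationError, match="disease_duration_at_baseline"):
        read_cohort(b, v)


def test_unknown_patient_in_visits_is_named(tmp_path):
    b = _write(tmp_path, "b.csv", BASELINE_CSV)
    v = _write(tmp_path, "v.csv", VISITS_CSV + "X9,0,40\nX9,2,40\n")
    with pytest.raises(CohortValidationError, match="X9"):
        read_cohort(b, v)


def test_duplicate_time_point_is_named(tmp_path):
    b = _write(tmp_path, "b.csv", BASELINE_CSV)
    v = _write(tmp_path, "v.csv", VISITS_CSV + "A,3,39\n")
    with pytest.raises(CohortValidationError, match="'A'"):
        read_cohort(b, v)


def test_nonpositive_nfl_row_rejected_with_reason(tmp_path):
    b = _write(tmp_path, "b.csv", BASELINE_CSV + "C,spinal,8,40,0\n")
    v = _write(tmp_path, "v.csv", VISITS_CSV)
    cohort, rejected = read_cohort(b, v)
    assert cohort.n_patients == 2
    assert len(rejected) == 1
    assert rejected[0].patient_id == "C"
    assert "non-positive NfL" in rejected[0].reason


def test_validate_cohort_clean_is_empty(tiny_cohort):
    assert validate_cohort(tiny_cohort) == []


def test_validate_cohort_reports_each_violation():
    """Validation is total: it reports score range, duplicated times and orphan patients."""
    baselines = [
        PatientBaseline(
            patient_id="A",
            onset_site=OnsetSite.SPINAL,
            disease_duration_at_baseline=10.0,
            alsfrs_r_at_baseline=42,
            nfl_at_baseline=100.0,
        )
    ]
    visits = [
        Visit(patient_id="A", months_since_baseline=0.0, alsfrs_r=50),
        Visit(patient_id="A", months_since_baseline=3.0, alsfrs_r=40),
        Visit(patient_id="A", months_since_baseline=3.0, alsfrs_r=39),
    ]
    issues = validate_cohort(Cohort(baselines=baselines, visits=visits))
    messages = " | ".join(i.message for i in issues)
    assert "out of range" in messages
    assert "duplicated time point" in messages
    assert len(issues) == 2


def test_validate_checks_onset_time_consistency():
    baselines = [
        PatientBaseline(
            patient_id="A",
            onset_site=OnsetSite.SPINAL,
            disease_duration_at_baseline=10.0,
            alsfrs_r_at_baseline=42,
            nfl_at_baseline=100.0,
        )
    ]
    visits = [
        Visit(patient_id="A", months_since_baseline=0.0, months_since_onset=10.0, alsfrs_r=42),
        Visit(patient_id="A", months_since_baseline=3.0, months_since_onset=20.0, alsfrs_r=40),
    ]
    issues = validate_cohort(Cohort(baselines=baselines, visits=visits))
    assert len(issues) == 1
    assert "inconsistent" in issues[0].message


def test_synthetic_cohort_round_trips_through_csv(tmp_path):
    """Field-for-field CSV round-trip on a generated cohort (optional covariates included)."""
    synth = generate_cohort(SyntheticConfig(n_patients=12, seed=11))
    write_cohort(synth.cohort, tmp_path / "b.csv", tmp_path / "v.csv")
    again, rejected = read_cohort(tmp_path / "b.csv", tmp_path / "v.csv")
    assert rejected == []
    assert len(again.baselines) == len(synth.cohort.baselines)
    for b1, b2 in zip(synth.cohort.baselines, again.baselines):
        assert b1.patient_id == b2.patient_id
        assert b1.onset_site == b2.onset_site
        assert b1.sex == b2.sex
        assert b1.alsfrs_r_at_baseline == b2.alsfrs_r_at_baseline
        assert b1.nfl_at_baseline == pytest.approx(b2.nfl_at_baseline)
        assert b1.bmi == pytest.approx(b2.bmi)
    assert [v.alsfrs_r for v in again.visits] == [
        v.alsfrs_r
        for v in sorted(synth.cohort.visits, key=lambda x: (x.patient_id, x.months_since_baseline))
    ]
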