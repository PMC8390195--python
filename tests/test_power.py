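"""Mixed-effects power machinery: design assembly, fitting, savings, permutations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nflpower import (
    DomainError,
    InsufficientDataError,
    build_design,
    fit_power_models,
    permutation_power,
    saving_percent,
)
from nflpower.power import TrialDesign
from nflpower.synthetic import SyntheticConfig, generate_trial, simulate_power_design


def _small_trial(n=24, seed=0, **kwargs):
    return generate_trial(SyntheticConfig(n_patients=n, seed=seed, **kwargs))


def test_build_design_centers_time_per_patient(tiny_cohort):
    """Visits at 3/6/9 months become t = 0/3/6 with a1 = the month-3 score."""
    predictions = {"A": -0.5, "B": -1.0}
    assignment = {"A": 1, "B": 0}
    design = build_design(tiny_cohort, predictions, assignment)
    for pid in ("A", "B"):
        rows = design.frame[design.frame["patient_id"] == pid]
        assert sorted(rows["t"]) == [0.0, 3.0, 6.0]
        month3_score = rows.loc[rows["t"] == 0.0, "a"].iloc[0]
        assert (rows["a1"] == month3_score).all()


def test_build_design_excludes_underobserved_patients():
    """A patient with a single interventional visit is excluded and listed."""
    synth = _small_trial(n=6, seed=4)
    cohort = synth.cohort
    victim = cohort.patient_ids[0]
    cohort.visits = [
        v for v in cohort.visits if not (v.patient_id == victim and v.months_since_baseline > 3)
    ]
    preds = synth.true_slopes
    assignment = {pid: i % 2 for i, pid in enumerate(cohort.patient_ids)}
    design = build_design(cohort, preds, assignment)
    assert victim in design.excluded
    assert victim not in set(design.frame["patient_id"])


def test_build_design_rejects_single_arm(tiny_cohort):
    with pytest.raises(InsufficientDataError, match="single-arm"):
        build_design(tiny_cohort, {"A": -0.5, "B": -1.0}, {"A": 1, "B": 1})


@pytest.mark.parametrize(
    "se_alt, se_null, expected",
    [(0.2, 0.2, 0.0), (0.2 / np.sqrt(2), 0.2, 50.0), (0.1, 0.2, 75.0)],
)
def test_saving_percent_values(se_alt, se_null, expected):
    assert saving_percent(se_alt, se_null) == pytest.approx(expected, abs=1e-10)


def test_saving_percent_rejects_nonpositive_se():
    with pytest.raises(DomainError):
        saving_percent(0.0, 0.1)


@settings(derandomize=True, max_examples=200)
@given(
    se_null=st.floats(1e-3, 10),
    f1=st.floats(0.01, 3),
    f2=st.floats(0.01, 3),
)
def test_saving_percent_strictly_decreasing_in_se_alt(se_null, f1, f2):
    lo, hi = sorted((f1 * se_null, f2 * se_null))
    if lo == hi:
        return
    assert saving_percent(lo, se_null) > saving_percent(hi, se_null)


def test_mixed_model_parameter_recovery_single_fit():
    """Fitting data simulated from the model recovers β2 and the variance components."""
    frame = simulate_power_design(
        n_patients=200, beta=(0.0, -0.8, 0.3, 0.0, 1.0),
        random_slope_sd=0.45, residual_sd=1.5, seed=11,
    )
    alt, null = fit_power_models(TrialDesign(frame=frame, excluded=[]))
    assert alt.converged and null.converged
    assert abs(alt.beta["t:treatment"] - 0.3) < 2 * alt.se_beta2
    assert alt.random_slope_sd == pytest.approx(0.45, rel=0.3)
    assert alt.residual_sd == pytest.approx(1.5, rel=0.3)


def test_degenerate_constant_predictions_drop_p_terms():
    frame = simulate_power_design(n_patients=40, seed=2)
    frame["p"] = -0.8
    with pytest.warns(UserWarning, match="constant"):
        alt, null = fit_power_models(TrialDesign(frame=frame, excluded=[]))
    assert alt.p_terms_dropped
    assert alt.se_beta2 == pytest.approx(null.se_beta2)
    assert saving_percent(alt.se_beta2, null.se_beta2) == pytest.approx(0.0)


def test_arm_flip_symmetry():
    """Relabelling arms flips β2's sign but leaves its standard error unchanged."""
    frame = simulate_power_design(n_patients=60, beta=(0.0, -0.8, 0.4, 0.0, 1.0), seed=5)
    alt, _ = fit_power_models(TrialDesign(frame=frame, excluded=[]))
    flipped = frame.assign(treatment=1 - frame["treatment"])
    alt_f, _ = fit_power_models(TrialDesign(frame=flipped, excluded=[]))
    assert alt_f.se_beta2 == pytest.approx(alt.se_beta2, rel=1e-4)
    assert alt_f.beta["t:treatment"] == pytest.approx(-alt.beta["t:treatment"], abs=1e-3)


def test_permutation_power_reproducible_bit_for_bit():
    synth = _small_trial(n=16, seed=9)
    preds = synth.true_slopes
    a = permutation_power(synth.cohort, preds, n_perm=20, seed=77)
    b = permutation_power(synth.cohort, preds, n_perm=20, seed=77)
    np.testing.assert_array_equal(a.savings, b.savings)
    assert a.as_dict() == b.as_dict()


def test_permutation_power_needs_four_patients():
    synth = _small_trial(n=3, seed=1)
    with pytest.raises(InsufficientDataError):
        permutation_power(synth.cohort, synth.true_slopes, n_perm=5, seed=1)


def test_monotone_information_ordering():
    """Oracle ≥ noisy oracle ≥ pure-noise predictions, in median saving."""
    synth = _small_trial(n=30, seed=14, score_noise_sd=1.0)
    oracle = synth.true_slopes
    rng = np.random.default_rng(6)
    noisy = {k: v + rng.normal(0, 0.4) for k, v in oracle.items()}
    values = list(oracle.values())
    noise = dict(zip(oracle.keys(), rng.permutation(values)))
    medians = [
        permutation_power(synth.cohort, preds, n_perm=60, seed=5).central_median
        for preds in (oracle, noisy, noise)
    ]
    assert medians[0] >= medians[1] >= medians[2]
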