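"""The published NfL model, its derived quantities, and model development."""

import math

import numpy as np
import pandas as pd
import pytest

from nflpower import (
    DomainError,
    NflModelCoefficients,
    NflSlopeRegressor,
    PUBLISHED_COEFFICIENTS,
    candidate_predictors,
    cohort_slopes,
    crossover_nfl,
    develop_model,
    ln_nfl_sensitivity,
    predict_slope,
)
from nflpower.slopes import SlopeEstimate
from nflpower.synthetic import SyntheticConfig, generate_cohort

TRUE_TERMS = {"ln_nfl", "onset_site", "ln_nfl:onset_site"}


def _truth_design(seed: int, n: int = 200):
    """Cohort covariates with slopes drawn directly from the model formula."""
    synth = generate_cohort(SyntheticConfig(n_patients=n, seed=seed))
    X = candidate_predictors(synth.cohort)
    truth = synth.truth.set_index("patient_id")
    X["ln_nfl"] = truth["ln_nfl"]  # the level the slopes were generated from
    slopes = [SlopeEstimate(pid, s, 0.0, 2) for pid, s in truth["true_slope"].items()]
    return X, slopes, truth


def test_worked_example_100_pg_ml():
    """At 100 pg/ml both onset sites predict −0.75 pt/month."""
    assert predict_slope(100.0, "spinal") == pytest.approx(-0.75, abs=0.005)
    assert predict_slope(100.0, "bulbar") == pytest.approx(-0.75, abs=0.005)


def test_intercept_only_at_unit_nfl():
    assert predict_slope(1.0, "bulbar") == pytest.approx(4.45)


def test_predict_rejects_nonpositive_nfl():
    with pytest.raises(DomainError):
        predict_slope(0.0, "spinal")


def test_predict_monotone_decreasing_and_bulbar_steeper():
    """Predictions fall with NfL for both sites; the bulbar line is steeper."""
    nfl = np.exp(np.linspace(2.5, 6.5, 40))
    for site in ("spinal", "bulbar"):
        preds = [predict_slope(x, site) for x in nfl]
        assert all(a > b for a, b in zip(preds, preds[1:]))
    assert abs(PUBLISHED_COEFFICIENTS.effective_ln_nfl_coef("bulbar")) > abs(
        PUBLISHED_COEFFICIENTS.effective_ln_nfl_coef("spinal")
    )


@pytest.mark.parametrize(
    "target, site, expected",
    [(0.5, "spinal", 1.67), (0.5, "bulbar", 0.44), (0.0, "spinal", 0.0)],
)
def test_ln_nfl_sensitivity(target, site, expected):
    assert ln_nfl_sensitivity(target, site) == pytest.approx(expected, abs=0.005)


def test_sensitivity_undefined_for_zero_coefficient():
    flat = NflModelCoefficients(1.0, 0.0, 0.5, 0.0)
    with pytest.raises(DomainError):
        ln_nfl_sensitivity(0.5, "bulbar", flat)


def test_crossover_nfl_closed_form():
    value = crossover_nfl()
    assert value == pytest.approx(math.exp(3.82 / 0.83), rel=1e-12)
    assert value == pytest.approx(99.7, abs=0.05)
    assert round(value, -1) == 100  # 2 significant figures
    # at the crossover the two sites' predictions coincide
    assert predict_slope(value, "spinal") == pytest.approx(predict_slope(value, "bulbar"), abs=1e-12)


def test_crossover_degenerate_cases():
    assert crossover_nfl(NflModelCoefficients(0, -1, 0.0, -0.8)) == pytest.approx(1.0)
    with pytest.raises(DomainError, match="no crossover"):
        crossover_nfl(NflModelCoefficients(0, -1, 0.5, 0.0))
    with pytest.raises(DomainError, match="every NfL"):
        crossover_nfl(NflModelCoefficients(0, -1, 0.0, 0.0))


def test_develop_model_retains_true_terms_on_generated_data():
    """On model-generated slopes the elimination keeps NfL, site, and their interaction."""
    X, slopes, _ = _truth_design(seed=42)
    result = develop_model(slopes, X)
    assert TRUE_TERMS <= set(result.fit.terms)
    assert result.fit.r == pytest.approx(math.sqrt(max(result.fit.adjusted_r2, 0)))
    # the removal trace records one (term, p-value) per eliminated term
    eliminated = {term for term, _ in result.elimination_trace}
    assert eliminated.isdisjoint(TRUE_TERMS)


def test_develop_model_on_pure_noise_eliminates_almost_everything(rng):
    """With slopes independent of all candidates, per-term retention stays near alpha."""
    retained_counts = []
    for seed in range(30):
        synth = generate_cohort(SyntheticConfig(n_patients=200, seed=seed))
        X = candidate_predictors(synth.cohort)
        noise_rng = np.random.default_rng(1000 + seed)
        slopes = [
            SlopeEstimate(pid, float(s), 0.0, 2)
            for pid, s in zip(X.index, noise_rng.normal(-0.8, 0.5, len(X)))
        ]
        result = develop_model(slopes, X)
        retained_counts.append(len(result.fit.terms) - 1)
    # 9 candidates * alpha = 0.45 expected retained terms per seed
    assert np.mean(retained_counts) < 1.2
    assert sum(c == 0 for c in retained_counts) >= 10


def test_subsets_with_ln_nfl_outrank_those_without():
    """Every subset gains adjusted R² when ln(NfL) joins it, on model-generated data."""
    X, slopes, _ = _truth_design(seed=7)
    result = develop_model(slopes, X)
    ranking = result.subset_ranking
    by_terms = {frozenset(t.split("+")): r2 for t, r2 in
                zip(ranking["terms"], ranking["adjusted_r2"])}
    checked = 0
    for subset, r2 in by_terms.items():
        if "ln_nfl" in subset or "ln_nfl:onset_site" in subset:
            continue
        with_nfl = by_terms.get(subset | {"ln_nfl"})
        if with_nfl is not None:
            assert with_nfl > r2
            checked += 1
    assert checked >= 30


def test_hierarchy_interaction_requires_parents():
    """No ranked subset contains the interaction without both parents."""
    X, slopes, _ = _truth_design(seed=3)
    result = develop_model(slopes, X)
    for terms in result.subset_ranking["terms"]:
        parts = set(terms.split("+"))
        if "ln_nfl:onset_site" in parts:
            assert {"ln_nfl", "onset_site"} <= parts
    # parents retained in the final model alongside the interaction
    assert TRUE_TERMS <= set(result.fit.terms)


def test_rank_deficient_design_is_reported():
    X, slopes, _ = _truth_design(seed=5)
    X["dup"] = X["ln_nfl"]
    with pytest.raises(ValueError, match="rank-deficient"):
        NflSlopeRegressor(candidate_terms=("ln_nfl", "dup")).fit(X, [s.slope for s in slopes])


def test_develop_model_drops_and_reports_incomplete_patients():
    X, slopes, _ = _truth_design(seed=9)
    X.loc[X.index[0], "bmi"] = np.nan
    result = develop_model(slopes, X)
    assert result.dropped_patients == [X.index[0]]
    assert result.fit.n == len(X) - 1


def test_estimator_sklearn_contract():
    """get_params/set_params round-trip and predict matches the design algebra."""
    X, slopes, _ = _truth_design(seed=1, n=120)
    est = NflSlopeRegressor(rank_subsets=False)
    assert est.get_params()["alpha"] == 0.05
    est.set_params(alpha=0.1)
    y = np.array([s.slope for s in slopes])
    est.fit(X, y)
    preds = est.predict(X)
    manual = np.full(len(X), est.params_["intercept"])
    for term in est.terms_:
        col = np.ones(len(X))
        for part in term.split(":"):
            col = col * X[part].to_numpy()
        manual += est.params_[term] * col
    np.testing.assert_allclose(preds, manual, atol=1e-10)


def test_refit_coefficients_roundtrip_through_prediction():
    """A fit exported as NfL-model coefficients predicts identically to the estimator."""
    X, slopes, _ = _truth_design(seed=13)
    est = NflSlopeRegressor(
        candidate_terms=("ln_nfl", "onset_site", "ln_nfl:onset_site"), rank_subsets=False
    ).fit(X, [s.slope for s in slopes])
    coefs = est.to_coefficients()
    for ln_value, site in ((4.0, "spinal"), (5.5, "bulbar")):
        frame = pd.DataFrame(
            {"ln_nfl": [ln_value], "onset_site": [1.0 if site == "spinal" else 0.0]}
        )
        assert predict_slope(math.exp(ln_value), site, coefs) == pytest.approx(
            float(est.predict(frame)[0]), abs=1e-10
        )
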