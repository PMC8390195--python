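"""Trial-size savings from prognostic covariate adjustment, via mixed models.

For a virtual placebo-controlled trial the interventional-period scores are
modelled with a linear mixed-effects model (REML),

    a_ij = a_i1 + b0 + b_i t_ij + b1 t_ij + b2 t_ij treatment_i
                + b3 p_i + b4 p_i t_ij,

where a_ij is patient i's ALSFRS-R score at time t_ij (months since the
interventional period start, centered to 0 per patient), a_i1 the score at
the first interventional time point entering as a fixed unit-coefficient
offset, b_i a per-patient Gaussian random slope (no random intercept), and
p_i the patient's predicted slope.  b2 measures the treatment effect.  The
null model drops both terms involving p_i.  The percent trial-size saving a
prediction method buys is

    100 * (1 - (SE_alt / SE_null)^2)

with SE_* the standard error of b2 in each model.  Because the placebo
cohorts carry no real treatment, treatment labels are assigned at random in
equal-sized arms, and the saving's distribution over many such permutations
yields a Monte-Carlo 95% CI (2.5/97.5% quantiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .errors import DomainError, InsufficientDataError
from .slopes import DEFAULT_LEAD_IN_MONTHS

__all__ = [
    "TrialDesign",
    "MixedModelFit",
    "PowerResult",
    "build_design",
    "fit_power_models",
    "saving_percent",
    "permutation_power",
]


@dataclass
class TrialDesign:
    """Long-format design rows for the mixed-effects power model.

    ``frame`` columns: patient_id, t (months since interventional start,
    0 at each patient's first retained visit), a (ALSFRS-R points), a1
    (points at t = 0, constant within patient), treatment (0/1), p
    (predicted slope, pt/month).
    """

    frame: pd.DataFrame
    excluded: list[str]


@dataclass(frozen=True)
class MixedModelFit:
    """Fixed effects and variance components of one fitted power model."""

    beta: dict[str, float]  # term -> estimate
    se_beta2: float  # SE of the treatment-by-time coefficient
    random_slope_sd: float
    residual_sd: float
    converged: bool
    p_terms_dropped: bool = False  # degenerate (constant) predictions


@dataclass
class PowerResult:
    """Permutation distribution of trial-size savings and its Monte-Carlo CI."""

    savings: np.ndarray  # one % per converged permutation
    central_mean: float
    central_median: float
    ci_low: float  # 2.5% quantile
    ci_high: float  # 97.5% quantile
    n_requested: int
    n_converged: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "central_mean": self.central_mean,
            "central_median": self.central_median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "seed": self.seed,
        }


def _interventional_rows(
    cohort: Cohort,
    predictions: Mapping[str, float],
    lead_in_months: float,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-visit rows for the interventional period, centered per patient."""
    rows = []
    excluded: list[str] = []
    for pid in cohort.patient_ids:
        if pid not in predictions:
            excluded.append(pid)
            continue
        visits = [
            v for v in cohort.visits_for(pid) if v.months_since_baseline >= lead_in_months
        ]
        times = sorted({v.months_since_baseline for v in visits})
        if len(times) < 2:
            excluded.append(pid)
            continue
        t0 = times[0]
        a1 = next(v.alsfrs_r for v in visits if v.months_since_baseline == t0)
        for v in visits:
            rows.append(
                {
                    "patient_id": pid,
                    "t": v.months_since_baseline - t0,
                    "a": float(v.alsfrs_r),
                    "a1": float(a1),
                    "p": float(predictions[pid]),
                }
            )
    return pd.DataFrame(rows), excluded


def build_design(
    cohort: Cohort,
    predictions: Mapping[str, float],
    assignment: Mapping[str, int],
    lead_in_months: float = DEFAULT_LEAD_IN_MONTHS,
) -> TrialDesign:
    """Assemble mixed-model rows for one treatment assignment.

    Patients without a prediction, without an assignment, or with fewer than
    two interventional time points are excluded and listed.
    """
    frame, excluded = _interventional_rows(cohort, predictions, lead_in_months)
    if len(frame):
        known = frame["patient_id"].isin(assignment.keys())
        excluded += sorted(set(frame.loc[~known, "patient_id"]))
        frame = frame.loc[known].copy()
    if not len(frame):
        raise InsufficientDataError("empty design: no patient has a prediction, an "
                                    "assignment and >= 2 interventional time points")
    frame["treatment"] = frame["patient_id"].map(assignment).astype(int)
    arms = set(frame["treatment"])
    if arms != {0, 1}:
        raise InsufficientDataError(f"single-arm design (all treatment = {arms.pop()})")
    frame = frame[["patient_id", "t", "a", "a1", "treatment", "p"]].reset_index(drop=True)
    return TrialDesign(frame=frame, excluded=excluded)


def _fit_one(
    y: np.ndarray,
    exog: np.ndarray,
    names: Sequence[str],
    groups: np.ndarray,
    t: np.ndarray,
    treat_index: int,
) -> MixedModelFit:
    model = sm.MixedLM(y, exog, groups=groups, exog_re=t[:, None])
    # gradient-based fitting can hit a singular score matrix when the random
    # slope variance collapses to the boundary; fall back to Powell then
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        try:
            res = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError):
            pass
        if res is None or not getattr(res, "converged", True):
            try:
                res = model.fit(reml=True, method="powell")
            except (np.linalg.LinAlgError, ValueError):
                res = None
        if res is None:
            return MixedModelFit({}, float("nan"), float("nan"), float("nan"), False)
    converged = bool(getattr(res, "converged", True))
    se2 = float(res.bse_fe[treat_index])
    if not np.isfinite(se2) or se2 <= 0:
        converged = False
    return MixedModelFit(
        beta=dict(zip(names, map(float, res.fe_params))),
        se_beta2=se2,
        random_slope_sd=float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(res.scale)),
        converged=converged,
    )


def fit_power_models(design: TrialDesign) -> tuple[MixedModelFit, MixedModelFit]:
    """Fit the full (alt) and prediction-free (null) power models by REML.

    The offset a_i1 is absorbed by modelling a_ij − a_i1 with the same fixed
    and random structure, which is algebraically identical to a fixed
    unit-coefficient offset.  If the predictions are constant across patients
    the p and p×t columns are dropped from the alt model with a warning.
    """
    frame = design.frame
    for arm in (0, 1):
        if frame.loc[frame["treatment"] == arm, "patient_id"].nunique() < 2:
            raise InsufficientDataError(f"fewer than 2 patients in arm {arm}")
    y = (frame["a"] - frame["a1"]).to_numpy(dtype=float)
    t = frame["t"].to_numpy(dtype=float)
    treat = frame["treatment"].to_numpy(dtype=float)
    p = frame["p"].to_numpy(dtype=float)
    groups = frame["patient_id"].to_numpy()

    null_exog = np.column_stack([np.ones_like(t), t, t * treat])
    null_names = ["intercept", "t", "t:treatment"]
    null_fit = _fit_one(y, null_exog, null_names, groups, t, treat_index=2)

    degenerate = np.ptp(p) == 0
    if degenerate:
        warnings.warn(
            "predictions are constant across patients; p terms dropped from the alt model",
            stacklevel=2,
        )
        alt_fit = MixedModelFit(
            beta=null_fit.beta,
            se_beta2=null_fit.se_beta2,
            random_slope_sd=null_fit.random_slope_sd,
            residual_sd=null_fit.residual_sd,
            converged=null_fit.converged,
            p_terms_dropped=True,
        )
    else:
        alt_exog = np.column_stack([np.ones_like(t), t, t * treat, p, p * t])
        alt_names = ["intercept", "t", "t:treatment", "p", "p:t"]
        alt_fit = _fit_one(y, alt_exog, alt_names, groups, t, treat_index=2)
    return alt_fit, null_fit


def saving_percent(se_alt: float, se_null: float) -> float:
    """Percent trial-size saving implied by the shrinkage of SE(b2)."""
    if not (se_alt > 0 and se_null > 0):
        raise DomainError(f"standard errors must be positive (got {se_alt}, {se_null})")
    return 100.0 * (1.0 - (se_alt / se_null) ** 2)


def _equal_split(ids: Sequence[str], rng: np.random.Generator) -> dict[str, int]:
    """Random equal-arm split; with odd n the larger arm's side is uniform."""
    order = rng.permutation(len(ids))
    half = len(ids) // 2
    if len(ids) % 2 == 1 and rng.random() < 0.5:
        half += 1
    out = {}
    for rank, idx in enumerate(order):
        out[ids[idx]] = 1 if rank < half else 0
    return out


def permutation_power(
    cohort: Cohort,
    predictions: Mapping[str, float],
    n_perm: int = 10_000,
    seed: int = 0,
    lead_in_months: float = DEFAULT_LEAD_IN_MONTHS,
    shuffle_predictions: bool = False,
) -> PowerResult:
    """Permutation Monte-Carlo distribution of trial-size savings.

    Each permutation draws a fresh equal-split treatment assignment, fits the
    alt and null mixed models, and records the saving.  Permutations where
    either model fails to converge are dropped and counted.  The RNG is a
    seeded counter-based generator (Philox) so results are platform-stable
    and bit-for-bit reproducible for a given seed.

    With ``shuffle_predictions`` the prediction-to-patient mapping is also
    re-permuted in every permutation, which destroys the predictor's
    information while keeping its marginal distribution: the resulting
    savings distribution is the uninformative-predictor null and should
    cover 0.
    """
    frame, excluded = _interventional_rows(cohort, predictions, lead_in_months)
    ids = sorted(frame["patient_id"].unique()) if len(frame) else []
    if len(ids) < 4:
        raise InsufficientDataError(
            f"need >= 4 evaluable patients for permutation power (got {len(ids)})"
        )
    rng = np.random.Generator(np.random.Philox(seed))

    y = (frame["a"] - frame["a1"]).to_numpy(dtype=float)
    t = frame["t"].to_numpy(dtype=float)
    p = frame["p"].to_numpy(dtype=float)
    groups = frame["patient_id"].to_numpy()
    degenerate = np.ptp(p) == 0

    pred_values = np.asarray([predictions[pid] for pid in ids], dtype=float)
    savings: list[float] = []
    n_failed = 0
    for _ in range(n_perm):
        if shuffle_predictions:
            shuffled = dict(zip(ids, rng.permutation(pred_values)))
            p = frame["patient_id"].map(shuffled).to_numpy(dtype=float)
        assignment = _equal_split(ids, rng)
        treat = frame["patient_id"].map(assignment).to_numpy(dtype=float)
        null_fit = _fit_one(
            y,
            np.column_stack([np.ones_like(t), t, t * treat]),
            ["intercept", "t", "t:treatment"],
            groups,
            t,
            treat_index=2,
        )
        if degenerate:
            alt_fit = null_fit
        else:
            alt_fit = _fit_one(
                y,
                np.column_stack([np.ones_like(t), t, t * treat, p, p * t]),
                ["intercept", "t", "t:treatment", "p", "p:t"],
                groups,
                t,
                treat_index=2,
            )
        if not (alt_fit.converged and null_fit.converged):
            n_failed += 1
            continue
        savings.append(saving_percent(alt_fit.se_beta2, null_fit.se_beta2))

    if not savings:
        raise InsufficientDataError("no permutation produced a converged model pair")
    if n_failed:
        warnings.warn(
            f"{n_failed}/{n_perm} permutations failed to converge and were dropped",
            stacklevel=2,
        )
    arr = np.asarray(savings, dtype=float)
    return PowerResult(
        savings=arr,
        central_mean=float(arr.mean()),
        central_median=float(np.median(arr)),
        ci_low=float(np.quantile(arr, 0.025)),
        ci_high=float(np.quantile(arr, 0.975)),
        n_requested=n_perm,
        n_converged=len(savings),
        seed=seed,
    )
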