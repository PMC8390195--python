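"""The NfL progression-rate model: published coefficients and model development.

The prediction model maps a patient's baseline blood neurofilament light
chain level (NfL, pg/ml) and site of disease onset (S = 1 spinal, 0 bulbar)
to a predicted ALSFRS-R slope (pt/month):

    slope = b0 + b1*ln(NfL) + b2*S + b3*S*ln(NfL)

with published coefficients (4.45, -1.13, -3.82, 0.83) shipped as
:data:`PUBLISHED_COEFFICIENTS`.  Model development re-derives such a model
from per-patient slopes and candidate baseline covariates via backward
elimination of non-significant terms, with an all-subsets adjusted-R²
ranking as a cross-check; :class:`NflSlopeRegressor` is the scikit-learn
style estimator implementing the procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, OnsetSite, Sex
from .errors import DomainError, InsufficientDataError
from .slopes import SlopeEstimate, delta_frs

__all__ = [
    "NflModelCoefficients",
    "PUBLISHED_COEFFICIENTS",
    "RegressionFit",
    "NflSlopeRegressor",
    "DEFAULT_CANDIDATE_TERMS",
    "predict_slope",
    "ln_nfl_sensitivity",
    "crossover_nfl",
    "candidate_predictors",
    "develop_model",
    "ModelDevelopmentResult",
]


@dataclass(frozen=True)
class NflModelCoefficients:
    """Coefficients of the site-interaction NfL model, all in pt/month units."""

    intercept: float
    coef_ln_nfl: float  # per ln(pg/ml)
    coef_spinal: float  # coefficient of S
    coef_interaction: float  # per ln(pg/ml), coefficient of S*ln(NfL)

    def effective_ln_nfl_coef(self, onset_site: OnsetSite | str) -> float:
        """Slope change per ln(NfL) unit for the given onset site."""
        s = 1.0 if OnsetSite(onset_site) is OnsetSite.SPINAL else 0.0
        return self.coef_ln_nfl + s * self.coef_interaction


#: The published model: slope = 4.45 - 1.13 ln(NfL) - 3.82 S + 0.83 S ln(NfL)
PUBLISHED_COEFFICIENTS = NflModelCoefficients(
    intercept=4.45, coef_ln_nfl=-1.13, coef_spinal=-3.82, coef_interaction=0.83
)


def predict_slope(
    nfl_pg_ml: float | np.ndarray,
    onset_site: OnsetSite | str | np.ndarray,
    coefficients: NflModelCoefficients = PUBLISHED_COEFFICIENTS,
) -> float | np.ndarray:
    """Predicted ALSFRS-R slope (pt/month) from baseline NfL and onset site.

    Accepts scalars or aligned arrays; ``onset_site`` may be the enum,
    "spinal"/"bulbar" strings, or a 0/1 spinal indicator array.
    """
    nfl = np.asarray(nfl_pg_ml, dtype=float)
    if np.any(nfl <= 0):
        raise DomainError("NfL must be positive (its natural log must be defined)")
    if isinstance(onset_site, (OnsetSite, str)):
        s = 1.0 if OnsetSite(onset_site) is OnsetSite.SPINAL else 0.0
    else:
        s = np.asarray(onset_site, dtype=float)
    ln = np.log(nfl)
    out = (
        coefficients.intercept
        + coefficients.coef_ln_nfl * ln
        + coefficients.coef_spinal * s
        + coefficients.coef_interaction * s * ln
    )
    return float(out) if np.isscalar(nfl_pg_ml) or np.ndim(out) == 0 else out


def ln_nfl_sensitivity(
    target_slope_change: float,
    onset_site: OnsetSite | str,
    coefficients: NflModelCoefficients = PUBLISHED_COEFFICIENTS,
) -> float:
    """ln(NfL) change (log units) producing a given predicted-slope change.

    For spinal onset the effective coefficient is the sum of the main and
    interaction ln(NfL) coefficients; for bulbar onset it is the main
    coefficient alone.
    """
    eff = coefficients.effective_ln_nfl_coef(onset_site)
    if target_slope_change == 0:
        return 0.0
    if eff == 0:
        raise DomainError(
            "effective ln(NfL) coefficient is zero for this onset site; sensitivity undefined"
        )
    return abs(target_slope_change / eff)


def crossover_nfl(coefficients: NflModelCoefficients = PUBLISHED_COEFFICIENTS) -> float:
    """NfL concentration (pg/ml) where spinal and bulbar predictions coincide.

    Solving b2*S + b3*S*ln(NfL) = 0 for S = 1 gives ln(NfL) = -b2/b3.
    """
    if coefficients.coef_interaction == 0:
        if coefficients.coef_spinal == 0:
            raise DomainError("site and interaction coefficients are both zero: "
                              "predictions coincide at every NfL level")
        raise DomainError("zero interaction with nonzero site effect: no crossover exists")
    return float(math.exp(-coefficients.coef_spinal / coefficients.coef_interaction))


# ---------------------------------------------------------------------------
# model development
# ---------------------------------------------------------------------------

#: the eight candidate main effects plus the single NfL-by-site interaction
DEFAULT_CANDIDATE_TERMS = (
    "ln_nfl",
    "onset_site",
    "sex",
    "age",
    "bmi",
    "disease_duration",
    "delta_frs",
    "alsfrs_r_at_baseline",
    "ln_nfl:onset_site",
)


@dataclass(frozen=True)
class RegressionFit:
    """A fitted multivariable linear model with term-level inference."""

    terms: tuple[str, ...]  # includes "intercept" first
    estimates: tuple[float, ...]
    standard_errors: tuple[float, ...]
    p_values: tuple[float, ...]
    adjusted_r2: float
    r: float  # sqrt(max(adjusted_r2, 0))
    n: int

    def as_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "estimates": list(self.estimates),
            "standard_errors": list(self.standard_errors),
            "p_values": list(self.p_values),
            "adjusted_r2": self.adjusted_r2,
            "r": self.r,
            "n": self.n,
        }


def _parse_term(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def _term_column(X: pd.DataFrame, term: str) -> np.ndarray:
    parts = _parse_term(term)
    col = np.ones(len(X))
    for p in parts:
        col = col * X[p].to_numpy(dtype=float)
    return col


def _hierarchy_valid(subset: Sequence[str]) -> bool:
    present = set(subset)
    for term in subset:
        parts = _parse_term(term)
        if len(parts) > 1 and not all(p in present for p in parts):
            return False
    return True


class NflSlopeRegressor(RegressorMixin, BaseEstimator):
    """Backward-elimination linear model for ALSFRS-R slope prediction.

    Starting from all candidate terms, the non-significant term with the
    largest coefficient p-value is removed one at a time until every
    remaining non-intercept term is significant at ``alpha``.  Hierarchy is
    enforced: an interaction is only ever included alongside both parents,
    and a parent of a retained interaction is never removed.  An all-subsets
    comparison (partial F-test of each hierarchy-valid subset against the
    intercept-only model, ranked by adjusted R², ties broken by fewer terms)
    is computed alongside as a model-selection cross-check.

    Parameters
    ----------
    candidate_terms : sequence of str, default DEFAULT_CANDIDATE_TERMS
        Column names of ``X`` to consider; interactions as "a:b" products.
    alpha : float, default 0.05
        Two-sided significance level for coefficient retention.
    rank_subsets : bool, default True
        Whether to compute the all-subsets ranking (disable for speed in
        repeated simulation).

    Attributes
    ----------
    terms_ : tuple of str
        Retained non-intercept terms, in design order.
    params_, bse_, pvalues_ : dict
        Estimate, standard error and two-sided p-value per term (incl.
        "intercept").
    adjusted_r2_, r_ : float
        Goodness of fit of the final model and its square root.
    elimination_trace_ : list of (term, p_value)
        Terms in removal order with the p-value at removal.
    subset_ranking_ : pandas.DataFrame or None
        Columns: terms, n_terms, adjusted_r2, f_statistic, f_pvalue.
    """

    def __init__(
        self,
        candidate_terms: Sequence[str] = DEFAULT_CANDIDATE_TERMS,
        alpha: float = 0.05,
        rank_subsets: bool = True,
    ):
        self.candidate_terms = candidate_terms
        self.alpha = alpha
        self.rank_subsets = rank_subsets

    # -- fitting ------------------------------------------------------------

    def _design(self, X: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
        cols = [np.ones(len(X))] + [_term_column(X, t) for t in terms]
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y) -> "NflSlopeRegressor":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with named candidate columns")
        terms = list(self.candidate_terms)
        needed = sorted({p for t in terms for p in _parse_term(t)})
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise KeyError(f"X lacks candidate columns: {missing}")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(X[needed].to_numpy(dtype=float))) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite with no missing values")
        n = len(y)
        if n <= len(terms) + 1:
            raise InsufficientDataError(
                f"need n > {len(terms) + 1} observations for {len(terms)} candidate terms (got {n})"
            )

        design = self._design(X, terms)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "rank-deficient design among candidate terms: " + ", ".join(terms)
            )

        trace: list[tuple[str, float]] = []
        current = terms
        while True:
            res = sm.OLS(y, self._design(X, current)).fit()
            pvals = dict(zip(current, res.pvalues[1:]))
            # parents of a retained interaction are protected
            protected = {
                p
                for t in current
                for p in _parse_term(t)
                if len(_parse_term(t)) > 1
            }
            removable = {t: p for t, p in pvals.items() if t not in protected}
            if not removable:
                break
            worst = max(removable, key=removable.get)
            if removable[worst] < self.alpha:
                break
            trace.append((worst, float(removable[worst])))
            current = [t for t in current if t != worst]
            if not current:
                res = sm.OLS(y, np.ones((n, 1))).fit()
                break

        self.terms_ = tuple(current)
        names = ("intercept", *current)
        self.params_ = dict(zip(names, map(float, res.params)))
        self.bse_ = dict(zip(names, map(float, res.bse)))
        self.pvalues_ = dict(zip(names, map(float, res.pvalues)))
        self.adjusted_r2_ = float(res.rsquared_adj) if current else 0.0
        self.r_ = math.sqrt(max(self.adjusted_r2_, 0.0))
        self.elimination_trace_ = trace
        self.n_ = n
        self.feature_names_in_ = np.asarray(needed, dtype=object)
        self.n_features_in_ = len(needed)
        self.subset_ranking_ = self._rank_subsets(X, y, terms) if self.rank_subsets else None
        return self

    def _rank_subsets(self, X: pd.DataFrame, y: np.ndarray, terms: Sequence[str]) -> pd.DataFrame:
        n = len(y)
        tss = float(np.sum((y - y.mean()) ** 2))
        columns = {t: _term_column(X, t) for t in terms}
        rows = []
        for k in range(1, len(terms) + 1):
            for subset in itertools.combinations(terms, k):
                if not _hierarchy_valid(subset):
                    continue
                design = np.column_stack([np.ones(n)] + [columns[t] for t in subset])
                beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
                if rank < design.shape[1]:
                    continue
                rss = float(np.sum((y - design @ beta) ** 2))
                p = len(subset)
                r2 = 1.0 - rss / tss if tss > 0 else 0.0
                adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
                if rss > 0 and n - p - 1 > 0:
                    f = ((tss - rss) / p) / (rss / (n - p - 1))
                    fp = float(stats.f.sf(f, p, n - p - 1))
                else:
                    f, fp = math.inf, 0.0
                rows.append(
                    {
                        "terms": "+".join(subset),
                        "n_terms": p,
                        "adjusted_r2": adj,
                        "f_statistic": f,
                        "f_pvalue": fp,
                    }
                )
        frame = pd.DataFrame(rows)
        return frame.sort_values(
            ["adjusted_r2", "n_terms"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)

    # -- prediction ---------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "terms_")
        design = self._design(X, self.terms_)
        beta = np.asarray([self.params_["intercept"], *(self.params_[t] for t in self.terms_)])
        return design @ beta

    # -- views --------------------------------------------------------------

    def to_regression_fit(self) -> RegressionFit:
        check_is_fitted(self, "terms_")
        names = ("intercept", *self.terms_)
        return RegressionFit(
            terms=names,
            estimates=tuple(self.params_[t] for t in names),
            standard_errors=tuple(self.bse_[t] for t in names),
            p_values=tuple(self.pvalues_[t] for t in names),
            adjusted_r2=self.adjusted_r2_,
            r=self.r_,
            n=self.n_,
        )

    def to_coefficients(self) -> NflModelCoefficients:
        """Express the fit as NfL-model coefficients (absent terms are zero).

        Only valid when the retained terms are a subset of
        {ln_nfl, onset_site, ln_nfl:onset_site}.
        """
        check_is_fitted(self, "terms_")
        allowed = {"ln_nfl", "onset_site", "ln_nfl:onset_site"}
        extra = set(self.terms_) - allowed
        if extra:
            raise ValueError(f"fit retains terms outside the NfL-model form: {sorted(extra)}")
        return NflModelCoefficients(
            intercept=self.params_["intercept"],
            coef_ln_nfl=self.params_.get("ln_nfl", 0.0),
            coef_spinal=self.params_.get("onset_site", 0.0),
            coef_interaction=self.params_.get("ln_nfl:onset_site", 0.0),
        )


# ---------------------------------------------------------------------------
# cohort-level wrappers
# ---------------------------------------------------------------------------


def candidate_predictors(cohort: Cohort) -> pd.DataFrame:
    """Per-patient candidate-predictor table for model development.

    Columns: ln_nfl, onset_site (1 spinal / 0 bulbar), sex (1 male /
    0 female), age (years at onset), bmi, disease_duration (months),
    delta_frs (signed, i.e. negated decline rate, comparable to the slope
    outcome), alsfrs_r_at_baseline.  Missing optional covariates become NaN.
    """
    rows = []
    for b in cohort.baselines:
        rows.append(
            {
                "patient_id": b.patient_id,
                "ln_nfl": math.log(b.nfl_at_baseline),
                "onset_site": 1.0 if b.onset_site is OnsetSite.SPINAL else 0.0,
                "sex": (1.0 if b.sex is Sex.MALE else 0.0) if b.sex is not None else np.nan,
                "age": b.age_at_onset if b.age_at_onset is not None else np.nan,
                "bmi": b.bmi if b.bmi is not None else np.nan,
                "disease_duration": b.disease_duration_at_baseline,
                "delta_frs": delta_frs(
                    b.alsfrs_r_at_baseline, b.disease_duration_at_baseline, b.patient_id
                ).as_slope_prediction,
                "alsfrs_r_at_baseline": float(b.alsfrs_r_at_baseline),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


@dataclass
class ModelDevelopmentResult:
    fit: RegressionFit
    elimination_trace: list[tuple[str, float]]
    subset_ranking: pd.DataFrame | None
    dropped_patients: list[str]
    estimator: NflSlopeRegressor


def develop_model(
    slopes: Sequence[SlopeEstimate],
    predictors: pd.DataFrame,
    candidate_terms: Sequence[str] = DEFAULT_CANDIDATE_TERMS,
    alpha: float = 0.05,
    rank_subsets: bool = True,
) -> ModelDevelopmentResult:
    """Develop the prediction model on per-patient slopes and covariates.

    Patients with missing values among the candidate columns are dropped and
    reported in ``dropped_patients``.
    """
    slope_by_id = {s.patient_id: s.slope for s in slopes}
    frame = predictors.loc[[pid for pid in predictors.index if pid in slope_by_id]].copy()
    needed = sorted({p for t in candidate_terms for p in _parse_term(t)})
    complete = frame[needed].notna().all(axis=1)
    dropped = [str(pid) for pid in frame.index[~complete]]
    frame = frame.loc[complete]
    y = np.asarray([slope_by_id[pid] for pid in frame.index], dtype=float)
    est = NflSlopeRegressor(
        candidate_terms=candidate_terms, alpha=alpha, rank_subsets=rank_subsets
    ).fit(frame, y)
    return ModelDevelopmentResult(
        fit=est.to_regression_fit(),
        elimination_trace=est.elimination_trace_,
        subset_ranking=est.subset_ranking_,
        dropped_patients=dropped,
        estimator=est,
    )
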