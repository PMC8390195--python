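"""External-validation metrics for predicted vs observed progression rates.

Observed values y are the per-patient OLS slopes over the interventional
period; predictions p come from one of three methods: the NfL model applied
to baseline NfL and onset site, the negated ΔFRS decline rate, or the slope
over the lead-in period.  Metrics:

    RMSE            sqrt(mean((y - p)^2))
    CoefD           1 - sum((y - p)^2) / sum((y - mean(y))^2)   (<= 1)
    variance change (var(y - p) - var(y)) / var(y)              (>= -1)

CoefD is a coefficient of determination of the predictions: 1 means perfect
prediction, 0 matches always-predict-the-mean, negative means worse than the
mean.  A negative variance change means the predictions explain slope
heterogeneity (more statistical power in a trial); sample variances use the
n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import Cohort
from .errors import InsufficientDataError, UndefinedMetricError
from .model import NflModelCoefficients, PUBLISHED_COEFFICIENTS, predict_slope
from .slopes import DEFAULT_LEAD_IN_MONTHS, cohort_slopes, delta_frs

__all__ = [
    "EvalMetrics",
    "PredictionMethod",
    "rmse",
    "coefd",
    "variance_change",
    "frac_within_tol",
    "paired_predictions",
    "evaluate_method",
]

PredictionMethod = Literal["nfl_model", "delta_frs", "lead_in"]

DEFAULT_TOL = 0.5  # pt/month, the "correct prediction" band


@dataclass(frozen=True)
class EvalMetrics:
    rmse: float
    coefd: float
    variance_change: float
    frac_within_tol: float
    tol: float
    n: int
    n_dropped: int = 0


def _pair(observed: Sequence[float], predicted: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} observed vs {p.shape} predicted")
    return y, p


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error of predictions, pt/month."""
    y, p = _pair(observed, predicted)
    if y.size < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((y - p) ** 2)))


def coefd(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination of predictions against observed slopes."""
    y, p = _pair(observed, predicted)
    if y.size < 2:
        raise ValueError("need at least two pairs")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise UndefinedMetricError("observed slopes are all identical; CoefD undefined")
    return float(1.0 - np.sum((y - p) ** 2) / denom)


def variance_change(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Relative change of residual variance vs observed-slope variance."""
    y, p = _pair(observed, predicted)
    if y.size < 2:
        raise ValueError("need at least two pairs")
    vy = float(np.var(y, ddof=1))
    if vy == 0:
        raise UndefinedMetricError("observed slopes have zero variance; metric undefined")
    return float((np.var(y - p, ddof=1) - vy) / vy)


def frac_within_tol(
    observed: Sequence[float], predicted: Sequence[float], tol: float = DEFAULT_TOL
) -> float:
    """Fraction of patients with |observed - predicted| <= tol pt/month."""
    y, p = _pair(observed, predicted)
    if y.size < 1:
        raise ValueError("need at least one pair")
    return float(np.mean(np.abs(y - p) <= tol))


def paired_predictions(
    cohort: Cohort,
    method: PredictionMethod,
    coefficients: NflModelCoefficients = PUBLISHED_COEFFICIENTS,
    lead_in_months: float = DEFAULT_LEAD_IN_MONTHS,
) -> tuple[list[str], np.ndarray, np.ndarray, int]:
    """Observed interventional slopes paired with one method's predictions.

    Returns (patient_ids, observed, predicted, n_dropped); patients lacking
    the inputs the method needs (e.g. a valid lead-in slope) are dropped and
    counted, never silently aligned across methods.
    """
    observed_est, excluded = cohort_slopes(
        cohort, period="interventional", lead_in_months=lead_in_months
    )
    obs_by_id = {e.patient_id: e.slope for e in observed_est}
    dropped = len(excluded)

    ids: list[str] = []
    preds: list[float] = []
    if method == "lead_in":
        lead_est, lead_excluded = cohort_slopes(
            cohort, period="lead_in", lead_in_months=lead_in_months
        )
        lead_by_id = {e.patient_id: e.slope for e in lead_est}
        for pid in obs_by_id:
            if pid in lead_by_id:
                ids.append(pid)
                preds.append(lead_by_id[pid])
            else:
                dropped += 1
    elif method == "delta_frs":
        for pid in obs_by_id:
            b = cohort.baseline(pid)
            preds.append(
                delta_frs(b.alsfrs_r_at_baseline, b.disease_duration_at_baseline, pid).as_slope_prediction
            )
            ids.append(pid)
    elif method == "nfl_model":
        for pid in obs_by_id:
            b = cohort.baseline(pid)
            preds.append(predict_slope(b.nfl_at_baseline, b.onset_site, coefficients))
            ids.append(pid)
    else:
        raise ValueError(f"unknown prediction method {method!r}")

    y = np.asarray([obs_by_id[pid] for pid in ids], dtype=float)
    return ids, y, np.asarray(preds, dtype=float), dropped


def evaluate_method(
    cohort: Cohort,
    method: PredictionMethod,
    coefficients: NflModelCoefficients = PUBLISHED_COEFFICIENTS,
    lead_in_months: float = DEFAULT_LEAD_IN_MONTHS,
    tol: float = DEFAULT_TOL,
) -> EvalMetrics:
    """Score one prediction method on a cohort's interventional slopes."""
    ids, y, p, dropped = paired_predictions(cohort, method, coefficients, lead_in_months)
    if len(ids) < 2:
        raise InsufficientDataError(
            f"method '{method}': only {len(ids)} evaluable patients (need >= 2)"
        )
    return EvalMetrics(
        rmse=rmse(y, p),
        coefd=coefd(y, p),
        variance_change=variance_change(y, p),
        frac_within_tol=frac_within_tol(y, p, tol),
        tol=tol,
        n=len(ids),
        n_dropped=dropped,
    )
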