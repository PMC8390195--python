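"""Per-patient ALSFRS-R slope estimation, ΔFRS, and trial-period splitting.

The progression-rate outcome throughout the package is the per-patient OLS
slope of the ALSFRS-R sum score over time (pt/month; negative = decline).
ΔFRS is the historical proxy (48 − baseline score) / months since symptom
onset, stored positive (a decline rate) and negated whenever it is used as a
prediction of a signed slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .cohort import ALSFRS_R_MAX, Cohort
from .errors import DomainError, InsufficientDataError

__all__ = [
    "SlopeEstimate",
    "DeltaFRS",
    "fit_patient_slope",
    "delta_frs",
    "split_periods",
    "cohort_slopes",
]

Period = Literal["full_followup", "lead_in", "interventional"]
TimeOrigin = Literal["onset", "baseline", "interventional_start"]

DEFAULT_LEAD_IN_MONTHS = 3.0


@dataclass(frozen=True)
class SlopeEstimate:
    """A per-patient OLS progression rate over a named follow-up period."""

    patient_id: str
    slope: float  # pt/month, negative = functional decline
    intercept: float  # points at the period's time origin
    n_points: int
    period: Period = "full_followup"
    time_origin: TimeOrigin = "baseline"


@dataclass(frozen=True)
class DeltaFRS:
    """ΔFRS decline rate, stored positive (pt/month lost since onset)."""

    patient_id: str
    value: float  # >= 0

    @property
    def as_slope_prediction(self) -> float:
        """ΔFRS negated, on the signed-slope scale used by the models."""
        return -self.value


def fit_patient_slope(
    visits: Iterable[tuple[float, float]],
    patient_id: str = "",
    period: Period = "full_followup",
    time_origin: TimeOrigin = "baseline",
) -> SlopeEstimate:
    """Ordinary-least-squares slope of ALSFRS-R score over time.

    Parameters
    ----------
    visits
        Ordered (time in months, score in points) pairs; at least two pairs
        with at least two distinct times.

    Raises
    ------
    InsufficientDataError
        Fewer than two visits at distinct times.
    """
    pairs = list(visits)
    t = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if len(pairs) < 2 or np.unique(t).size < 2:
        raise InsufficientDataError(
            f"patient '{patient_id}': need >= 2 visits at distinct times to fit a slope "
            f"(got {len(pairs)} visits, {np.unique(t).size} distinct times)"
        )
    slope, intercept = np.polyfit(t, y, 1)
    return SlopeEstimate(
        patient_id=patient_id,
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(pairs),
        period=period,
        time_origin=time_origin,
    )


def delta_frs(
    alsfrs_r_at_baseline: float, disease_duration_at_baseline: float, patient_id: str = ""
) -> DeltaFRS:
    """ΔFRS = (48 − baseline score) / months from symptom onset to baseline.

    Equals the negated two-point slope through (0, 48) at onset and
    (duration, score) at baseline, assuming full function at symptom onset.
    """
    if disease_duration_at_baseline <= 0:
        raise DomainError(
            f"patient '{patient_id}': disease duration must be positive "
            f"(got {disease_duration_at_baseline})"
        )
    if not 0 <= alsfrs_r_at_baseline <= ALSFRS_R_MAX:
        raise DomainError(
            f"patient '{patient_id}': baseline score {alsfrs_r_at_baseline} out of [0, {ALSFRS_R_MAX}]"
        )
    value = (ALSFRS_R_MAX - alsfrs_r_at_baseline) / disease_duration_at_baseline
    return DeltaFRS(patient_id=patient_id, value=float(value))


def split_periods(
    visits: Iterable[tuple[float, float]], lead_in_months: float = DEFAULT_LEAD_IN_MONTHS
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Split trial visits into lead-in and interventional periods.

    Visit times are months since trial baseline.  The lead-in holds visits at
    t <= lead_in_months; the interventional period holds visits at
    t >= lead_in_months with times re-centered to start at 0.  A visit exactly
    at the boundary belongs to both periods: a trial's month-3 assessment is
    both the lead-in's end and the interventional period's first point.
    """
    pairs = sorted(visits, key=lambda p: p[0])
    lead_in = [(t, s) for t, s in pairs if t <= lead_in_months]
    interventional = [(t - lead_in_months, s) for t, s in pairs if t >= lead_in_months]
    return lead_in, interventional


def cohort_slopes(
    cohort: Cohort,
    period: Period = "full_followup",
    lead_in_months: float = DEFAULT_LEAD_IN_MONTHS,
    time_origin: TimeOrigin | None = None,
) -> tuple[list[SlopeEstimate], list[str]]:
    """Fit the requested period's slope for every patient in a cohort.

    For ``full_followup`` the regressor is time since symptom onset when the
    visits carry it (observational cohorts) and time since baseline otherwise;
    the slope itself is invariant to that shift.  ``lead_in`` and
    ``interventional`` use trial time, split at ``lead_in_months``.

    Returns the slope estimates plus the ids of patients excluded for having
    fewer than two distinct time points in the requested period.
    """
    estimates: list[SlopeEstimate] = []
    excluded: list[str] = []
    for pid in cohort.patient_ids:
        pvisits = cohort.visits_for(pid)
        if period == "full_followup":
            use_onset = all(v.months_since_onset is not None for v in pvisits)
            origin: TimeOrigin = time_origin or ("onset" if use_onset else "baseline")
            if origin == "onset" and use_onset:
                pairs = [(v.months_since_onset, float(v.alsfrs_r)) for v in pvisits]
            else:
                origin = "baseline"
                pairs = [(v.months_since_baseline, float(v.alsfrs_r)) for v in pvisits]
        else:
            trial = [(v.months_since_baseline, float(v.alsfrs_r)) for v in pvisits]
            lead, inter = split_periods(trial, lead_in_months)
            pairs = lead if period == "lead_in" else inter
            origin = "baseline" if period == "lead_in" else "interventional_start"
        try:
            estimates.append(fit_patient_slope(pairs, pid, period=period, time_origin=origin))
        except InsufficientDataError:
            excluded.append(pid)
    return estimates, excluded
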