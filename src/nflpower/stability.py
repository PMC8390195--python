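"""Within-patient temporal stability of blood ln(NfL).

Per patient, the temporal fluctuation is summarised as the mean relative
deviation of each ln(NfL) measurement from the patient's mean ln(NfL),
expressed in percent.  Across patients the package reports the mean and SD
of these per-patient deviations, and the empirical 2.5/97.5 percentiles of
the raw difference between the first-follow-up and baseline ln(NfL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DomainError, InsufficientDataError

__all__ = ["StabilitySummary", "relative_deviation_per_patient", "stability_summary",
           "trajectory_table"]


@dataclass(frozen=True)
class StabilitySummary:
    mean_rel_dev_pct: float
    sd_rel_dev_pct: float
    diff_p2_5: float  # ln units, 2.5 percentile of followup1 - baseline
    diff_p97_5: float
    n_patients: int
    n_measurements: int


def relative_deviation_per_patient(nfl_series: Sequence[float]) -> float:
    """Mean relative deviation (%) of a patient's ln(NfL) from their mean.

    mean over measurements of |ln(NfL)_j − mean_i| / mean_i × 100, where
    mean_i is the patient's mean ln(NfL).  Requires >= 2 positive values.
    """
    values = np.asarray(nfl_series, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(f"need >= 2 NfL measurements (got {values.size})")
    if np.any(values <= 0):
        raise DomainError("NfL values must be positive")
    ln = np.log(values)
    mean = ln.mean()
    return float(np.mean(np.abs(ln - mean) / mean) * 100.0)


def _nfl_series(cohort: Cohort, patient_id: str) -> list[float]:
    return [
        v.nfl_pg_ml
        for v in cohort.visits_for(patient_id)
        if v.nfl_pg_ml is not None and v.nfl_pg_ml > 0
    ]


def stability_summary(cohort: Cohort) -> StabilitySummary:
    """Cohort-level ln(NfL) stability summary.

    Aggregation order is per-measurement deviations → per-patient mean →
    across-patient mean and SD.  The percentile band is over the signed
    difference (ln NfL at first follow-up − ln NfL at baseline) across
    patients, with linear interpolation between order statistics.  Patients
    with fewer than two NfL measurements are skipped.
    """
    rel_devs: list[float] = []
    diffs: list[float] = []
    n_measurements = 0
    for pid in cohort.patient_ids:
        series = _nfl_series(cohort, pid)
        if len(series) < 2:
            continue
        rel_devs.append(relative_deviation_per_patient(series))
        ln = np.log(series)
        diffs.append(float(ln[1] - ln[0]))
        n_measurements += len(series)
    if not rel_devs:
        raise InsufficientDataError("no patient has >= 2 NfL measurements")
    rel = np.asarray(rel_devs)
    d = np.asarray(diffs)
    return StabilitySummary(
        mean_rel_dev_pct=float(rel.mean()),
        sd_rel_dev_pct=float(rel.std(ddof=1)) if rel.size > 1 else 0.0,
        diff_p2_5=float(np.quantile(d, 0.025)),
        diff_p97_5=float(np.quantile(d, 0.975)),
        n_patients=len(rel_devs),
        n_measurements=n_measurements,
    )


def trajectory_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient ln(NfL) trajectories (patient, measurement index, ln NfL)."""
    rows = []
    for pid in cohort.patient_ids:
        for j, value in enumerate(_nfl_series(cohort, pid)):
            rows.append({"patient_id": pid, "measurement": j, "ln_nfl": float(np.log(value))})
    return pd.DataFrame(rows, columns=["patient_id", "measurement", "ln_nfl"])
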