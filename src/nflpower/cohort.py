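"""Cohort containers and CSV ingestion for longitudinal ALS records.

A cohort is a pair of tables: one row of baseline covariates per patient
(site of onset, baseline NfL, ALSFRS-R score at baseline, ...) and one row
per study visit (months since baseline, ALSFRS-R sum score, optionally a
blood NfL measurement).  Times are months throughout; fractional months are
allowed.  Missing optional covariates are ``None``, never sentinel numbers.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import CohortValidationError, ConfigurationError

__all__ = [
    "OnsetSite",
    "Sex",
    "PatientBaseline",
    "Visit",
    "Cohort",
    "RowIssue",
    "ValidationIssue",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "load_column_map",
]

ALSFRS_R_MAX = 48

#: tolerance (months) for the months_since_onset consistency check
_TIME_TOL = 0.51


class OnsetSite(str, enum.Enum):
    SPINAL = "spinal"
    BULBAR = "bulbar"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class PatientBaseline:
    """One patient's covariates at study baseline (time of diagnosis / entry)."""

    patient_id: str
    onset_site: OnsetSite
    disease_duration_at_baseline: float  # months since symptom onset, > 0
    alsfrs_r_at_baseline: int  # 0..48 sum score
    nfl_at_baseline: float  # pg/ml, > 0
    cohort_label: str = ""
    sex: Sex | None = None
    age_at_onset: float | None = None  # years
    bmi: float | None = None  # kg/m^2
    deceased: bool | None = None
    months_survived_since_onset: float | None = None


@dataclass(frozen=True)
class Visit:
    """One timestamped ALSFRS-R (and optionally NfL) measurement."""

    patient_id: str
    months_since_baseline: float  # >= 0
    alsfrs_r: int  # 0..48
    months_since_onset: float | None = None
    nfl_pg_ml: float | None = None  # > 0 when present


@dataclass
class Cohort:
    """A validated collection of baselines plus their longitudinal visits."""

    baselines: list[PatientBaseline]
    visits: list[Visit]
    label: str = ""

    def __post_init__(self) -> None:
        self._by_id = {b.patient_id: b for b in self.baselines}

    @property
    def patient_ids(self) -> list[str]:
        return [b.patient_id for b in self.baselines]

    @property
    def n_patients(self) -> int:
        return len(self.baselines)

    def baseline(self, patient_id: str) -> PatientBaseline:
        return self._by_id[patient_id]

    def visits_for(self, patient_id: str) -> list[Visit]:
        out = [v for v in self.visits if v.patient_id == patient_id]
        out.sort(key=lambda v: v.months_since_baseline)
        return out

    def baseline_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.baselines:
            row = {f.name: getattr(b, f.name) for f in dc_fields(b)}
            row["onset_site"] = b.onset_site.value
            row["sex"] = b.sex.value if b.sex is not None else None
            rows.append(row)
        return pd.DataFrame(rows, columns=[f.name for f in dc_fields(PatientBaseline)])

    def visit_frame(self) -> pd.DataFrame:
        rows = [{f.name: getattr(v, f.name) for f in dc_fields(v)} for v in self.visits]
        frame = pd.DataFrame(rows, columns=[f.name for f in dc_fields(Visit)])
        return frame.sort_values(["patient_id", "months_since_baseline"], kind="stable").reset_index(
            drop=True
        )


@dataclass(frozen=True)
class RowIssue:
    """One rejected input row and the reason it was rejected."""

    table: str  # "baseline" | "visits"
    row: int  # 0-based data row index
    patient_id: str
    reason: str


@dataclass(frozen=True)
class ValidationIssue:
    patient_id: str
    message: str


_BASELINE_REQUIRED = (
    "patient_id",
    "onset_site",
    "disease_duration_at_baseline",
    "alsfrs_r_at_baseline",
    "nfl_at_baseline",
)
_BASELINE_OPTIONAL = (
    "cohort_label",
    "sex",
    "age_at_onset",
    "bmi",
    "deceased",
    "months_survived_since_onset",
)
_VISIT_REQUIRED = ("patient_id", "months_since_baseline", "alsfrs_r")
_VISIT_OPTIONAL = ("months_since_onset", "nfl_pg_ml")


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a column map (canonical field -> file header) from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"column map in {path} must be a mapping")
    cmap = data.get("column_map", data)
    return {str(k): str(v) for k, v in cmap.items()}


def _resolve(frame: pd.DataFrame, required: Sequence[str], optional: Sequence[str],
             column_map: Mapping[str, str] | None, table: str) -> dict[str, str]:
    cmap = dict(column_map or {})
    resolved: dict[str, str] = {}
    for name in (*required, *optional):
        col = cmap.get(name, name)
        if col in frame.columns:
            resolved[name] = col
        elif name in required:
            raise ConfigurationError(
                f"required column '{name}' (mapped to '{col}') missing from {table} table"
            )
    return resolved


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(value)


def _parse_baseline_row(idx: int, row: pd.Series, cols: Mapping[str, str]) -> PatientBaseline:
    pid = str(row[cols["patient_id"]])
    site_raw = str(row[cols["onset_site"]]).strip().lower()
    try:
        site = OnsetSite(site_raw)
    except ValueError:
        raise ValueError(f"unknown onset site {site_raw!r}") from None
    duration = float(row[cols["disease_duration_at_baseline"]])
    if not duration > 0:
        raise ValueError("non-positive disease duration")
    score = int(round(float(row[cols["alsfrs_r_at_baseline"]])))
    if not 0 <= score <= ALSFRS_R_MAX:
        raise ValueError(f"ALSFRS-R score {score} out of range [0, {ALSFRS_R_MAX}]")
    nfl = float(row[cols["nfl_at_baseline"]])
    if not nfl > 0:
        raise ValueError("non-positive NfL")
    sex = None
    if "sex" in cols:
        raw = row[cols["sex"]]
        if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) and raw != "":
            sex = Sex(str(raw).strip().lower())
    return PatientBaseline(
        patient_id=pid,
        onset_site=site,
        disease_duration_at_baseline=duration,
        alsfrs_r_at_baseline=score,
        nfl_at_baseline=nfl,
        cohort_label=str(row[cols["cohort_label"]]) if "cohort_label" in cols and not pd.isna(row[cols["cohort_label"]]) else "",
        sex=sex,
        age_at_onset=_opt_float(row[cols["age_at_onset"]]) if "age_at_onset" in cols else None,
        bmi=_opt_float(row[cols["bmi"]]) if "bmi" in cols else None,
        deceased=_opt_bool(row[cols["deceased"]]) if "deceased" in cols else None,
        months_survived_since_onset=_opt_float(row[cols["months_survived_since_onset"]])
        if "months_survived_since_onset" in cols
        else None,
    )


def _parse_visit_row(idx: int, row: pd.Series, cols: Mapping[str, str]) -> Visit:
    pid = str(row[cols["patient_id"]])
    t = float(row[cols["months_since_baseline"]])
    if t < 0:
        raise ValueError("negative months_since_baseline")
    score = int(round(float(row[cols["alsfrs_r"]])))
    if not 0 <= score <= ALSFRS_R_MAX:
        raise ValueError(f"ALSFRS-R score {score} out of range [0, {ALSFRS_R_MAX}]")
    nfl = _opt_float(row[cols["nfl_pg_ml"]]) if "nfl_pg_ml" in cols else None
    if nfl is not None and not nfl > 0:
        raise ValueError("non-positive NfL")
    onset_t = _opt_float(row[cols["months_since_onset"]]) if "months_since_onset" in cols else None
    return Visit(
        patient_id=pid,
        months_since_baseline=t,
        alsfrs_r=score,
        months_since_onset=onset_t,
        nfl_pg_ml=nfl,
    )


def read_cohort(
    baseline_table: str | Path,
    visits_table: str | Path,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
) -> tuple[Cohort, list[RowIssue]]:
    """Read a cohort from two CSV files.

    Parameters
    ----------
    baseline_table, visits_table
        Comma-separated files with a header row (UTF-8).
    column_map
        Optional mapping of canonical field name -> file column header, so
        differently-headed supplementary tables can be ingested unedited.

    Returns
    -------
    (cohort, rejected)
        The validated cohort, and a per-row report of rejected rows (rows
        whose required fields fail to parse or violate an invariant).

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    CohortValidationError
        On referential-integrity failures: a visit referencing an unknown
        patient, or duplicated (patient, time) pairs.
    """
    bframe = pd.read_csv(baseline_table)
    vframe = pd.read_csv(visits_table)
    bcols = _resolve(bframe, _BASELINE_REQUIRED, _BASELINE_OPTIONAL, column_map, "baseline")
    vcols = _resolve(vframe, _VISIT_REQUIRED, _VISIT_OPTIONAL, column_map, "visits")

    rejected: list[RowIssue] = []
    baselines: list[PatientBaseline] = []
    seen_ids: set[str] = set()
    for idx, row in bframe.iterrows():
        pid = str(row[bcols["patient_id"]])
        try:
            parsed = _parse_baseline_row(idx, row, bcols)
        except (ValueError, TypeError, KeyError) as exc:
            rejected.append(RowIssue("baseline", int(idx), pid, str(exc)))
            continue
        if parsed.patient_id in seen_ids:
            raise CohortValidationError(f"duplicate patient_id '{parsed.patient_id}' in baseline table")
        seen_ids.add(parsed.patient_id)
        baselines.append(parsed)

    visits: list[Visit] = []
    seen_times: set[tuple[str, float]] = set()
    unknown: set[str] = set()
    for idx, row in vframe.iterrows():
        pid = str(row[vcols["patient_id"]])
        try:
            parsed = _parse_visit_row(idx, row, vcols)
        except (ValueError, TypeError, KeyError) as exc:
            rejected.append(RowIssue("visits", int(idx), pid, str(exc)))
            continue
        if parsed.patient_id not in seen_ids:
            unknown.add(parsed.patient_id)
            continue
        key = (parsed.patient_id, parsed.months_since_baseline)
        if key in seen_times:
            raise CohortValidationError(
                f"duplicate (patient, time) pair for patient '{parsed.patient_id}' "
                f"at {parsed.months_since_baseline} months"
            )
        seen_times.add(key)
        visits.append(parsed)

    if unknown:
        raise CohortValidationError(
            "visits reference unknown patient(s): " + ", ".join(sorted(unknown))
        )
    return Cohort(baselines=baselines, visits=visits, label=label), rejected


def write_cohort(cohort: Cohort, baseline_table: str | Path, visits_table: str | Path) -> None:
    """Write a cohort back to the two-CSV layout accepted by :func:`read_cohort`."""
    cohort.baseline_frame().to_csv(baseline_table, index=False)
    cohort.visit_frame().to_csv(visits_table, index=False)


def validate_cohort(cohort: Cohort) -> list[ValidationIssue]:
    """Report every invariant violation in a cohort; never raises.

    An empty report certifies that all cohort invariants hold.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for b in cohort.baselines:
        if b.patient_id in seen:
            issues.append(ValidationIssue(b.patient_id, "duplicate patient_id in baselines"))
        seen.add(b.patient_id)
        if not 0 <= b.alsfrs_r_at_baseline <= ALSFRS_R_MAX:
            issues.append(
                ValidationIssue(b.patient_id, f"baseline ALSFRS-R {b.alsfrs_r_at_baseline} out of range")
            )
        if not b.nfl_at_baseline > 0:
            issues.append(ValidationIssue(b.patient_id, "non-positive baseline NfL"))
        if not b.disease_duration_at_baseline > 0:
            issues.append(ValidationIssue(b.patient_id, "non-positive disease duration"))

    with_visits: set[str] = set()
    times: dict[str, set[float]] = {}
    for v in cohort.visits:
        if v.patient_id not in seen:
            issues.append(ValidationIssue(v.patient_id, "visit references unknown patient"))
            continue
        with_visits.add(v.patient_id)
        prev = times.setdefault(v.patient_id, set())
        if v.months_since_baseline in prev:
            issues.append(
                ValidationIssue(v.patient_id, f"duplicated time point at {v.months_since_baseline} months")
            )
        prev.add(v.months_since_baseline)
        if not 0 <= v.alsfrs_r <= ALSFRS_R_MAX:
            issues.append(ValidationIssue(v.patient_id, f"visit ALSFRS-R {v.alsfrs_r} out of range"))
        if v.nfl_pg_ml is not None and not v.nfl_pg_ml > 0:
            issues.append(ValidationIssue(v.patient_id, "non-positive visit NfL"))
        if v.months_since_onset is not None:
            b = cohort._by_id.get(v.patient_id)
            if b is not None:
                expected = v.months_since_baseline + b.disease_duration_at_baseline
                if abs(v.months_since_onset - expected) > _TIME_TOL:
                    issues.append(
                        ValidationIssue(
                            v.patient_id,
                            f"months_since_onset {v.months_since_onset} inconsistent with "
                            f"baseline time + disease duration ({expected:.2f})",
                        )
                    )
    for pid in seen - with_visits:
        issues.append(ValidationIssue(pid, "patient has no visits"))
    return issues
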