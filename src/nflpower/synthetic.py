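"""Synthetic ALS cohorts with the statistical structure the analysis assumes.

The generator emulates an observational/trial cohort: per patient a site of
onset (Bernoulli), a baseline ln(NfL) level (Gaussian on the log scale), a
true linear ALSFRS-R slope equal to the NfL-model prediction plus Gaussian
heterogeneity, integer visit scores obtained by rounding and clipping a
noisy linear trajectory to [0, 48], and longitudinal NfL measurements that
fluctuate multiplicatively around the patient's ln level.  Defaults match a
typical ALS development cohort at diagnosis: mean baseline ln(NfL) 4.63 (SD
0.81) pg/ml, 78% spinal onset, baseline score ~42, median disease duration
~10 months, visits every 3 months up to 18 months.  The per-patient true
slopes are returned alongside the cohort as a truth table, so downstream
estimators can be checked against the quantity they target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import ALSFRS_R_MAX, Cohort, OnsetSite, PatientBaseline, Sex, Visit
from .model import NflModelCoefficients, PUBLISHED_COEFFICIENTS, predict_slope

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_trial",
    "simulate_power_design",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_patients: int = 46
    prop_spinal: float = 0.78
    ln_nfl_mean: float = 4.63  # ln pg/ml
    ln_nfl_sd: float = 0.81
    true_coefficients: NflModelCoefficients = PUBLISHED_COEFFICIENTS
    slope_noise_sd: float = 0.45  # pt/month of slope heterogeneity beyond NfL/site
    score_noise_sd: float = 1.5  # points of per-visit measurement noise
    baseline_score_mean: float = 42.0
    baseline_score_sd: float = 2.0
    duration_median_months: float = 10.1
    duration_ln_sd: float = 0.8  # lognormal sigma; IQR not force-matched
    visit_interval_months: float = 3.0
    followup_months: float = 18.0
    nfl_rel_fluct_sd: float = 0.03  # fraction of the ln level
    treatment_effect: float = 0.0  # pt/month slowing added to treated patients
    integer_scores: bool = True  # round and clip visit scores to 0..48
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prop_spinal <= 1:
            raise ValueError("prop_spinal must lie in [0, 1]")
        for name in ("ln_nfl_sd", "slope_noise_sd", "score_noise_sd", "nfl_rel_fluct_sd",
                     "baseline_score_sd", "duration_ln_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.followup_months >= self.visit_interval_months > 0:
            raise ValueError("need followup_months >= visit_interval_months > 0")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its side-channel truth.

    ``truth`` has one row per patient: true_slope (pt/month, including any
    treatment shift), ln_nfl (the underlying baseline level), onset_site.
    ``assignment`` maps patient id -> 0/1 arm for generated trials.
    """

    cohort: Cohort
    truth: pd.DataFrame
    assignment: dict[str, int] | None = None

    @property
    def true_slopes(self) -> dict[str, float]:
        return dict(zip(self.truth["patient_id"], self.truth["true_slope"]))


def _generate(config: SyntheticConfig, randomize: bool) -> SyntheticCohort:
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    coef = config.true_coefficients

    site = rng.random(n) < config.prop_spinal
    ln_nfl0 = rng.normal(config.ln_nfl_mean, config.ln_nfl_sd, n)
    slope_noise = rng.normal(0.0, config.slope_noise_sd, n)
    base_score = np.clip(
        np.round(rng.normal(config.baseline_score_mean, config.baseline_score_sd, n)),
        0, ALSFRS_R_MAX,
    ).astype(int)
    duration = rng.lognormal(math.log(config.duration_median_months), config.duration_ln_sd, n)
    sex_male = rng.random(n) < 0.59
    age = rng.normal(60.1, 11.3, n)
    bmi = rng.normal(25.4, 2.5, n)

    arm = np.zeros(n, dtype=int)
    if randomize and n > 0:
        order = rng.permutation(n)
        arm[order[: n // 2]] = 1

    n_visits = int(math.floor(config.followup_months / config.visit_interval_months + 1e-9)) + 1
    times = np.arange(n_visits) * config.visit_interval_months

    baselines: list[PatientBaseline] = []
    visits: list[Visit] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i:04d}"
        true_slope = float(
            predict_slope(math.exp(ln_nfl0[i]), "spinal" if site[i] else "bulbar", coef)
            + slope_noise[i]
            + (config.treatment_effect if arm[i] == 1 else 0.0)
        )
        score_noise = rng.normal(0.0, config.score_noise_sd, n_visits)
        raw_scores = base_score[i] + true_slope * times + score_noise
        if config.integer_scores:
            scores = np.clip(np.round(raw_scores), 0, ALSFRS_R_MAX).astype(int)
        else:
            scores = raw_scores
        ln_fluct = ln_nfl0[i] * (1.0 + rng.normal(0.0, config.nfl_rel_fluct_sd, n_visits))
        nfl_baseline = float(np.exp(ln_fluct[0]))
        baselines.append(
            PatientBaseline(
                patient_id=pid,
                onset_site=OnsetSite.SPINAL if site[i] else OnsetSite.BULBAR,
                disease_duration_at_baseline=float(duration[i]),
                alsfrs_r_at_baseline=int(base_score[i]),
                nfl_at_baseline=nfl_baseline,
                cohort_label="synthetic",
                sex=Sex.MALE if sex_male[i] else Sex.FEMALE,
                age_at_onset=float(age[i]),
                bmi=float(bmi[i]),
            )
        )
        for j, t in enumerate(times):
            visits.append(
                Visit(
                    patient_id=pid,
                    months_since_baseline=float(t),
                    months_since_onset=float(t + duration[i]),
                    alsfrs_r=int(scores[j]) if config.integer_scores else float(scores[j]),
                    nfl_pg_ml=float(np.exp(ln_fluct[j])),
                )
            )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_slope": true_slope,
                "ln_nfl": float(ln_nfl0[i]),
                "onset_site": int(site[i]),
                "treatment": int(arm[i]),
            }
        )

    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "true_slope", "ln_nfl", "onset_site", "treatment"]
    )
    cohort = Cohort(baselines=baselines, visits=visits, label="synthetic")
    assignment = (
        dict(zip(truth["patient_id"], truth["treatment"])) if randomize else None
    )
    return SyntheticCohort(cohort=cohort, truth=truth, assignment=assignment)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate an observational cohort (no treatment arms)."""
    return _generate(config, randomize=False)


def generate_trial(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a 1:1 randomized virtual trial.

    Treated patients' true slope is shifted by ``config.treatment_effect``
    (positive = slower decline); everything else as :func:`generate_cohort`.
    """
    return _generate(config, randomize=True)


def simulate_power_design(
    n_patients: int = 60,
    n_visits: int = 7,
    visit_interval: float = 3.0,
    beta: tuple[float, float, float, float, float] = (0.0, -0.8, 0.0, 0.0, 1.0),
    random_slope_sd: float = 0.45,
    residual_sd: float = 1.5,
    prediction_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate data exactly from the mixed-effects power model.

    ``beta`` is (b0, b1, b2, b3, b4) of the model in :mod:`nflpower.power`;
    per-patient predictions p_i ~ Normal(b1, prediction_sd) and the random
    slope b_i ~ Normal(0, random_slope_sd) acts on top of the fixed time
    trend.  Returns a design frame with columns patient_id, t, a, a1,
    treatment, p suitable for :func:`nflpower.power.fit_power_models`.
    Treatment is a 1:1 split.  Used for parameter-recovery checks of the
    fitting machinery against known truth.
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3, b4 = beta
    t = np.arange(n_visits) * visit_interval
    a1_base = 40.0
    rows = []
    arm = np.zeros(n_patients, dtype=int)
    arm[rng.permutation(n_patients)[: n_patients // 2]] = 1
    p = rng.normal(b1, prediction_sd, n_patients)
    b_i = rng.normal(0.0, random_slope_sd, n_patients)
    for i in range(n_patients):
        eps = rng.normal(0.0, residual_sd, n_visits)
        a = (
            a1_base
            + b0
            + (b_i[i] + b1) * t
            + b2 * t * arm[i]
            + b3 * p[i]
            + b4 * p[i] * t
            + eps
        )
        for j in range(n_visits):
            rows.append(
                {
                    "patient_id": f"S{i:04d}",
                    "t": float(t[j]),
                    "a": float(a[j]),
                    "a1": float(a[0]),
                    "treatment": int(arm[i]),
                    "p": float(p[i]),
                }
            )
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML file mirroring its fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "true_coefficients" in data and isinstance(data["true_coefficients"], Mapping):
        data["true_coefficients"] = NflModelCoefficients(**data["true_coefficients"])
    return SyntheticConfig(**data)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    data = asdict(config)
    data["true_coefficients"] = asdict(config.true_coefficients)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
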