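"""End-to-end workflow: develop, validate, compare methods, quantify power.

Mirrors the intended use in trial design: develop (or load) the NfL model on
an observational cohort, predict each validation-cohort patient's slope from
baseline NfL and onset site, score the three prediction methods on the
interventional-period slopes, and run the permutation power analysis for
each method and cohort.  All randomness flows from one top-level seed
expanded deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .errors import InsufficientDataError
from .evaluation import EvalMetrics, evaluate_method, paired_predictions
from .model import (
    DEFAULT_CANDIDATE_TERMS,
    ModelDevelopmentResult,
    NflModelCoefficients,
    PUBLISHED_COEFFICIENTS,
    candidate_predictors,
    develop_model,
    predict_slope,
)
from .power import PowerResult, permutation_power
from .slopes import DEFAULT_LEAD_IN_MONTHS, cohort_slopes, delta_frs
from .stability import StabilitySummary, stability_summary

__all__ = ["WorkflowConfig", "WorkflowReport", "run_workflow", "method_predictions"]

METHODS = ("nfl_model", "delta_frs", "lead_in")


@dataclass(frozen=True)
class WorkflowConfig:
    n_perm: int = 10_000
    seed: int = 0
    lead_in_months: float = DEFAULT_LEAD_IN_MONTHS
    alpha: float = 0.05
    tol: float = 0.5  # pt/month accuracy band
    use_published_coefficients: bool = True  # else: the refit development model
    candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS


@dataclass
class WorkflowReport:
    development_fit: dict
    elimination_trace: list
    validation_metrics: dict  # cohort -> method -> EvalMetrics dict
    power: dict  # cohort -> method -> PowerResult dict
    stability: dict  # cohort -> StabilitySummary dict
    residual_tables: dict  # cohort -> per-patient observed/predicted frame
    coefficients_used: dict
    config: dict
    seed: int
    version: str = __version__

    def as_dict(self) -> dict:
        out = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "coefficients_used": self.coefficients_used,
            "development_fit": self.development_fit,
            "elimination_trace": self.elimination_trace,
            "validation_metrics": self.validation_metrics,
            "power": self.power,
            "stability": self.stability,
            "residuals": {
                label: frame.to_dict(orient="records")
                for label, frame in self.residual_tables.items()
            },
        }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def to_markdown(self) -> str:
        lines = [
            "# Workflow report",
            f"- package version: {self.version}",
            f"- seed: {self.seed}",
            "",
            "## Development fit",
            f"- terms: {', '.join(self.development_fit['terms'])}",
            f"- adjusted R2: {self.development_fit['adjusted_r2']:.3f} "
            f"(R = {self.development_fit['r']:.2f}), n = {self.development_fit['n']}",
            "",
            "## Validation metrics",
        ]
        for label, by_method in self.validation_metrics.items():
            lines.append(f"### {label}")
            for method, m in by_method.items():
                lines.append(
                    f"- {method}: RMSE {m['rmse']:.2f}, CoefD {m['coefd']:.2f}, "
                    f"variance change {m['variance_change']:+.2f}, "
                    f"within +/-{m['tol']} pt/m: {100 * m['frac_within_tol']:.0f}% (n={m['n']})"
                )
        lines.append("")
        lines.append("## Trial-size savings (permutation Monte Carlo)")
        for label, by_method in self.power.items():
            lines.append(f"### {label}")
            for method, p in by_method.items():
                lines.append(
                    f"- {method}: median {p['central_median']:.0f}% "
                    f"(mean {p['central_mean']:.0f}%), "
                    f"95% CI [{p['ci_low']:.0f}%, {p['ci_high']:.0f}%], "
                    f"{p['n_converged']}/{p['n_requested']} permutations"
                )
        return "\n".join(lines)


def method_predictions(
    cohort: Cohort,
    method: str,
    coefficients: NflModelCoefficients,
    lead_in_months: float,
) -> dict[str, float]:
    """Per-patient slope predictions for one method (no observed pairing)."""
    out: dict[str, float] = {}
    if method == "nfl_model":
        for b in cohort.baselines:
            out[b.patient_id] = predict_slope(b.nfl_at_baseline, b.onset_site, coefficients)
    elif method == "delta_frs":
        for b in cohort.baselines:
            out[b.patient_id] = delta_frs(
                b.alsfrs_r_at_baseline, b.disease_duration_at_baseline, b.patient_id
            ).as_slope_prediction
    elif method == "lead_in":
        estimates, _ = cohort_slopes(cohort, period="lead_in", lead_in_months=lead_in_months)
        out = {e.patient_id: e.slope for e in estimates}
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def _stage_seed(base_seed: int, *tags: str) -> int:
    """Stable per-stage child seed (< 2^31) derived from the top-level seed."""
    digest = hashlib.sha256("/".join(map(str, [base_seed, *tags])).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_workflow(
    dev_cohort: Cohort,
    validation_cohorts: Mapping[str, Cohort] | None = None,
    config: WorkflowConfig = WorkflowConfig(),
) -> WorkflowReport:
    """Run the full development → validation → power workflow.

    Returns a report whose every number is reproducible from the echoed
    configuration and seed.
    """
    validation_cohorts = dict(validation_cohorts or {})

    dev_slopes, _ = cohort_slopes(dev_cohort, period="full_followup")
    development = develop_model(
        dev_slopes,
        candidate_predictors(dev_cohort),
        candidate_terms=config.candidate_terms,
        alpha=config.alpha,
    )
    if config.use_published_coefficients:
        coefficients = PUBLISHED_COEFFICIENTS
    else:
        coefficients = development.estimator.to_coefficients()

    metrics: dict[str, dict] = {}
    power: dict[str, dict] = {}
    stability: dict[str, dict] = {}
    residuals: dict[str, pd.DataFrame] = {}
    for label, cohort in validation_cohorts.items():
        metrics[label] = {}
        power[label] = {}
        for method in METHODS:
            try:
                m = evaluate_method(
                    cohort, method, coefficients, config.lead_in_months, config.tol
                )
                metrics[label][method] = m.__dict__
            except InsufficientDataError as exc:
                metrics[label][method] = {"error": str(exc)}
            preds = method_predictions(cohort, method, coefficients, config.lead_in_months)
            try:
                p = permutation_power(
                    cohort,
                    preds,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, label, method),
                    lead_in_months=config.lead_in_months,
                )
                power[label][method] = p.as_dict()
            except InsufficientDataError as exc:
                power[label][method] = {"error": str(exc)}
        try:
            stability[label] = stability_summary(cohort).__dict__
        except InsufficientDataError as exc:
            stability[label] = {"error": str(exc)}
        # per-patient observed minus predicted differences (trial application step 4)
        ids, y, p_nfl, _ = paired_predictions(
            cohort, "nfl_model", coefficients, config.lead_in_months
        )
        residuals[label] = pd.DataFrame(
            {
                "patient_id": ids,
                "observed_slope": y,
                "predicted_slope": p_nfl,
                "observed_minus_predicted": y - p_nfl,
            }
        )

    coef_used = {
        "intercept": coefficients.intercept,
        "coef_ln_nfl": coefficients.coef_ln_nfl,
        "coef_spinal": coefficients.coef_spinal,
        "coef_interaction": coefficients.coef_interaction,
        "source": "published" if config.use_published_coefficients else "refit",
    }
    return WorkflowReport(
        development_fit=development.fit.as_dict(),
        elimination_trace=[list(t) for t in development.elimination_trace],
        validation_metrics=metrics,
        power=power,
        stability=stability,
        residual_tables=residuals,
        coefficients_used=coef_used,
        config={
            "n_perm": config.n_perm,
            "lead_in_months": config.lead_in_months,
            "alpha": config.alpha,
            "tol": config.tol,
            "use_published_coefficients": config.use_published_coefficients,
            "candidate_terms": list(config.candidate_terms),
        },
        seed=config.seed,
    )
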