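"""One simulated observational study, end to end.

A replicate draws a cohort of patients from the population, builds the noisy
severity score the investigator will adjust with, assigns treatment with
risk-weighted probabilities, applies the treatment's true odds ratio to the
treated patients' risks, draws one Bernoulli death per patient, and fits a
logistic regression of death on treatment (plus the severity score, unless
the analysis is unadjusted). The exponentiated treatment coefficient is the
study's measured odds ratio; a two-sided Wald test at alpha decides whether
the study "concludes" benefit, harm, or no effect.

Replicates that fail (perfect separation, a death vector with a single class,
a non-converged fit) are labelled degenerate and reported, never silently
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from ._rng import substream
from .adjuster import generate_adjuster
from .auroc import empirical_auroc
from .confounding import ConfoundingScenario, assign_treatment
from .errors import UndefinedAUROCError, ValidationError
from .population import PopulationModel, sample_cohort
from .treatment import apply_odds_ratio

__all__ = [
    "SimulationConfig",
    "ReplicateResult",
    "fit_logistic",
    "run_replicate",
    "run_cell",
    "classify_conclusion",
]


@dataclass
class SimulationConfig:
    """One cell of the simulation grid.

    ``adjuster_sigma`` is the calibrated noise level of the severity score;
    ``None`` means an unadjusted analysis (regression on treatment alone) and
    ``0.0`` means the investigator adjusts with the true risk itself (the
    intrinsic ceiling). ``target_auroc`` is a label carried through to the
    output (the AUROC the sigma was calibrated to, or "unadjusted" /
    "intrinsic").
    """

    population: PopulationModel
    scenario: ConfoundingScenario
    true_or: float = 1.0
    n: int = 1_000
    adjuster_sigma: float | None = 0.0
    target_auroc: float | str = "intrinsic"
    reps: int = 1_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 100:
            raise ValidationError("n must be at least 100 for regression stability")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.reps < 1:
            raise ValidationError("reps must be at least 1")
        if not self.true_or > 0:
            raise ValidationError("true_or must be positive")


@dataclass
class ReplicateResult:
    """Outcome of one simulated study."""

    measured_or: float
    p_value: float
    realized_auroc: float  # NaN for unadjusted analyses
    deaths: int
    treated: int
    conclusion: str  # benefit | null | harm | degenerate
    converged: bool
    replicate_index: int = 0


def fit_logistic(outcome: np.ndarray, covariates: np.ndarray):
    """Maximum-likelihood logistic fit with Wald standard errors.

    ``covariates`` excludes the intercept, which is added internally.

    Returns
    -------
    (coefficients, standard_errors, p_values, converged)
        Coefficient order: intercept first, then the covariate columns.
        On perfect separation or non-convergence, estimates are returned as
        NaN and ``converged`` is False.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValidationError("covariate with zero variance")
    design = sm.add_constant(X, has_constant="add")
    k = design.shape[1]
    nan = np.full(k, np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", False))
        # a separated fit can "converge" to huge coefficients; treat an
        # unbounded estimate as degenerate as well
        if converged and np.any(np.abs(res.params) > 30):
            converged = False
        if not converged:
            return nan, nan, nan, False
        return res.params, res.bse, res.pvalues, True
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return nan, nan, nan, False


def _conclusion(measured_or: float, p_value: float, alpha: float) -> str:
    if not np.isfinite(measured_or) or not np.isfinite(p_value):
        return "degenerate"
    if p_value < alpha:
        return "harm" if measured_or > 1.0 else "benefit"
    return "null"


def run_replicate(config: SimulationConfig, replicate_index: int) -> ReplicateResult:
    """Simulate one observational study; deterministic given (seed, index)."""
    rng = substream(config.seed, replicate_index)
    cohort = sample_cohort(config.population, config.n, rng)

    adjusted = config.adjuster_sigma is not None
    score = generate_adjuster(cohort, config.adjuster_sigma, rng) if adjusted else None

    treat = assign_treatment(cohort, config.scenario, rng)
    risk = np.where(
        treat == 1,
        apply_odds_ratio(cohort.baseline_risk, config.true_or),
        cohort.baseline_risk,
    )
    died = (rng.random(config.n) < risk).astype(np.int8)

    deaths = int(died.sum())
    treated = int(treat.sum())

    realized = np.nan
    if adjusted and 0 < deaths < config.n:
        try:
            realized = empirical_auroc(score, died)
        except UndefinedAUROCError:  # pragma: no cover
            realized = np.nan

    degenerate = ReplicateResult(
        measured_or=np.nan,
        p_value=np.nan,
        realized_auroc=realized,
        deaths=deaths,
        treated=treated,
        conclusion="degenerate",
        converged=False,
        replicate_index=replicate_index,
    )
    if deaths in (0, config.n) or treated in (0, config.n):
        return degenerate

    covariates = np.column_stack([treat, score]) if adjusted else treat[:, None].astype(float)
    coef, _, pvals, converged = fit_logistic(died, covariates)
    if not converged:
        return degenerate

    measured_or = float(np.exp(coef[1]))
    p_value = float(pvals[1])
    return ReplicateResult(
        measured_or=measured_or,
        p_value=p_value,
        realized_auroc=realized,
        deaths=deaths,
        treated=treated,
        conclusion=_conclusion(measured_or, p_value, config.alpha),
        converged=True,
        replicate_index=replicate_index,
    )


def run_cell(config: SimulationConfig) -> list[ReplicateResult]:
    """Run every replicate of one grid cell."""
    return [run_replicate(config, i) for i in range(config.reps)]


def classify_conclusion(result: ReplicateResult, true_or: float, alpha: float) -> str:
    """Label a replicate's conclusion against the truth.

    For a truly beneficial treatment (true OR < 1): ``true_benefit``,
    ``false_negative`` (no significant effect), or ``false_harm``. For a safe
    treatment (true OR = 1): ``true_null``, ``false_benefit``, or
    ``false_harm``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if true_or > 1:
        raise ValidationError("classification defined for true odds ratios <= 1")
    if result.conclusion == "degenerate":
        return "degenerate"
    p, orr = result.p_value, result.measured_or
    significant = p < alpha
    if true_or < 1:
        if not significant:
            return "false_negative"
        return "false_harm" if orr > 1 else "true_benefit"
    if not significant:
        return "true_null"
    return "false_harm" if orr > 1 else "false_benefit"
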