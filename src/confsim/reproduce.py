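"""Headline quantities of the simulation study, recomputed from scratch.

Each function here runs the full pipeline (population fit, scenario
calibration, adjuster-noise calibration, replicate simulation, aggregation)
for one of the study's headline results: the risk shift at the median
patient, the biased unadjusted mean odds ratios, the null significance rate,
the upper interval estimate under a null treatment, and the
adjuster-accuracy level at which the mean measured OR crosses 1.0. They are
used by the ``reproduce-headline`` CLI subcommand and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .adjuster import calibrate_sigma
from .confounding import ConfoundingScenario
from .engine import SimulationConfig, run_cell
from .population import PopulationModel, fit_unimodal
from .summary import find_crossing_auroc, summarize_cell
from .treatment import apply_odds_ratio

__all__ = [
    "risk_shift_percent",
    "mean_unadjusted_or",
    "null_significant_percent",
    "null_interval_upper",
    "crossing_auroc",
    "DEFAULT_AUROC_GRID",
]

#: Adjuster-accuracy targets named in the study's results, capped at the
#: unimodal population's intrinsic ceiling (~0.76).
DEFAULT_AUROC_GRID: tuple[float, ...] = (0.56, 0.60, 0.64, 0.66, 0.70, 0.72)


def _seed_for(root_seed: int, tag: int) -> int:
    """Derive an independent 31-bit cell seed from the root seed."""
    return int(
        np.random.SeedSequence(root_seed, spawn_key=(tag,)).generate_state(1)[0] % 2**31
    )


def risk_shift_percent(baseline_risk: float, true_or: float) -> int:
    """Post-treatment risk at a given baseline, as a rounded percentage."""
    return round(100.0 * apply_odds_ratio(baseline_risk, true_or))


def mean_unadjusted_or(
    population: PopulationModel,
    scenario: ConfoundingScenario,
    true_or: float,
    n: int = 10_000,
    reps: int = 200,
    seed: int = 0,
    tag: int = 0,
) -> float:
    """Mean measured OR from unadjusted regressions of death on treatment."""
    cfg = SimulationConfig(
        population=population,
        scenario=scenario,
        true_or=true_or,
        n=n,
        adjuster_sigma=None,
        target_auroc="unadjusted",
        reps=reps,
        seed=_seed_for(seed, tag),
    )
    s = summarize_cell(run_cell(cfg), true_or=true_or, n=n, scenario=scenario.name)
    return s.mean_or


def null_significant_percent(
    population: PopulationModel,
    n: int = 1_000,
    reps: int = 500,
    marginal_rate: float = 0.45,
    seed: int = 0,
    tag: int = 10,
) -> float:
    """Percent of adjusted studies of a safe treatment, with unconfounded
    assignment, that report a significant treatment coefficient (the type I
    error check: should sit near 100 * alpha)."""
    cfg = SimulationConfig(
        population=population,
        scenario=ConfoundingScenario.none(marginal_rate),
        true_or=1.0,
        n=n,
        adjuster_sigma=0.0,
        target_auroc="intrinsic",
        reps=reps,
        seed=_seed_for(seed, tag),
    )
    s = summarize_cell(run_cell(cfg), true_or=1.0, n=n, scenario="none")
    return 100.0 * s.significant_rate


def null_interval_upper(
    population: PopulationModel,
    scenario: ConfoundingScenario,
    target_auroc: float = 0.60,
    n: int = 1_000,
    reps: int = 500,
    seed: int = 0,
    tag: int = 20,
) -> float:
    """97.5th percentile of measured ORs for a truly null treatment."""
    adj = calibrate_sigma(population, target_auroc, n=n, reps=48, seed=_seed_for(seed, tag))
    cfg = SimulationConfig(
        population=population,
        scenario=scenario,
        true_or=1.0,
        n=n,
        adjuster_sigma=adj.sigma,
        target_auroc=target_auroc,
        reps=reps,
        seed=_seed_for(seed, tag + 1),
    )
    s = summarize_cell(run_cell(cfg), true_or=1.0, n=n, scenario=scenario.name)
    return s.interval_95[1]


def crossing_auroc(
    population: PopulationModel,
    scenario: ConfoundingScenario,
    true_or: float,
    n: int = 10_000,
    reps: int = 200,
    auroc_grid: tuple[float, ...] = DEFAULT_AUROC_GRID,
    seed: int = 0,
    tag: int = 30,
) -> float:
    """Adjuster AUROC at which the mean measured OR crosses 1.0."""
    summaries = []
    for j, target in enumerate(sorted(auroc_grid)):
        adj = calibrate_sigma(population, target, n=n, reps=16, seed=_seed_for(seed, tag + 2 * j))
        cfg = SimulationConfig(
            population=population,
            scenario=scenario,
            true_or=true_or,
            n=n,
            adjuster_sigma=adj.sigma,
            target_auroc=target,
            reps=reps,
            seed=_seed_for(seed, tag + 2 * j + 1),
        )
        summaries.append(
            summarize_cell(
                run_cell(cfg), true_or=true_or, n=n, scenario=scenario.name, target_auroc=target
            )
        )
    return find_crossing_auroc(summaries)
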