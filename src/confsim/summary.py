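"""Aggregation of replicate results into per-cell headline statistics.

For each cell of the parameter grid this module computes the quantities the
simulation is ultimately about: the false-negative rate (a truly beneficial
treatment reported as having no effect), the false-harm rate (a safe or
beneficial treatment reported as significantly increasing the odds of death),
and the distribution of measured odds ratios (mean, geometric mean, median,
IQR, and the 2.5th/97.5th percentile interval). Rates are proportions over
non-degenerate replicates; degenerate replicates are counted separately.

:func:`find_crossing_auroc` locates, by linear interpolation along the
adjuster-accuracy axis, the AUROC at which the mean measured OR crosses 1.0 —
the point where residual confounding exactly cancels a beneficial effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ReplicateResult, classify_conclusion
from .errors import ValidationError

__all__ = [
    "CellSummary",
    "summarize_cell",
    "find_crossing_auroc",
    "results_to_dataframe",
    "NO_CROSSING",
]

#: Sentinel returned when the mean-OR curve never brackets 1.0.
NO_CROSSING: float = float("nan")


@dataclass
class CellSummary:
    """Aggregates for one (n, true OR, scenario, target AUROC) cell."""

    n: int
    true_or: float
    scenario: str
    target_auroc: float | str
    reps_used: int
    degenerate_count: int
    false_negative_rate: float
    false_harm_rate: float
    false_benefit_rate: float
    significant_rate: float
    mean_or: float
    geometric_mean_or: float
    median_or: float
    iqr: tuple[float, float]
    interval_95: tuple[float, float]
    mean_realized_auroc: float = math.nan

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "true_or": self.true_or,
            "scenario": self.scenario,
            "target_auroc": self.target_auroc,
            "reps_used": self.reps_used,
            "degenerate_count": self.degenerate_count,
            "false_negative_rate": self.false_negative_rate,
            "false_harm_rate": self.false_harm_rate,
            "false_benefit_rate": self.false_benefit_rate,
            "significant_rate": self.significant_rate,
            "mean_or": self.mean_or,
            "geometric_mean_or": self.geometric_mean_or,
            "median_or": self.median_or,
            "iqr_low": self.iqr[0],
            "iqr_high": self.iqr[1],
            "interval_95_low": self.interval_95[0],
            "interval_95_high": self.interval_95[1],
            "mean_realized_auroc": self.mean_realized_auroc,
        }
        return d


def summarize_cell(
    results: list[ReplicateResult],
    true_or: float,
    alpha: float = 0.05,
    *,
    n: int = 0,
    scenario: str = "",
    target_auroc: float | str = "",
) -> CellSummary:
    """Aggregate one cell's replicates.

    Percentiles use linear interpolation between order statistics. Raises if
    every replicate is degenerate.
    """
    ok = [r for r in results if r.conclusion != "degenerate"]
    degenerate = len(results) - len(ok)
    if not ok:
        raise ValidationError(
            f"all {len(results)} replicates degenerate in cell "
            f"(n={n}, true_or={true_or}, scenario={scenario}, auroc={target_auroc})"
        )
    labels = [classify_conclusion(r, true_or, alpha) for r in ok]
    m = len(ok)
    ors = np.array([r.measured_or for r in ok])
    realized = np.array([r.realized_auroc for r in ok])

    q25, q50, q75 = np.percentile(ors, [25, 50, 75])
    lo95, hi95 = np.percentile(ors, [2.5, 97.5])
    return CellSummary(
        n=n,
        true_or=true_or,
        scenario=scenario,
        target_auroc=target_auroc,
        reps_used=m,
        degenerate_count=degenerate,
        false_negative_rate=labels.count("false_negative") / m,
        false_harm_rate=labels.count("false_harm") / m,
        false_benefit_rate=labels.count("false_benefit") / m,
        significant_rate=sum(r.p_value < alpha for r in ok) / m,
        mean_or=float(ors.mean()),
        geometric_mean_or=float(np.exp(np.log(ors).mean())),
        median_or=float(q50),
        iqr=(float(q25), float(q75)),
        interval_95=(float(lo95), float(hi95)),
        mean_realized_auroc=float(np.nanmean(realized)) if np.any(np.isfinite(realized)) else math.nan,
    )


def find_crossing_auroc(summaries: list[CellSummary]) -> float:
    """AUROC at which the mean measured OR crosses 1.0.

    ``summaries`` must be ordered by numeric target AUROC. Linear
    interpolation is applied on the first bracketing segment; if the curve
    never brackets 1.0, the NaN sentinel is returned.
    """
    pts = [(float(s.target_auroc), s.mean_or) for s in summaries]
    if len(pts) < 2:
        raise ValidationError("need at least two summaries to interpolate")
    if any(b[0] <= a[0] for a, b in zip(pts, pts[1:])):
        raise ValidationError("summaries must be strictly ordered by target_auroc")
    for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
        if (y1 - 1.0) == 0.0:
            return x1
        if (y1 - 1.0) * (y2 - 1.0) < 0:
            return x1 + (1.0 - y1) * (x2 - x1) / (y2 - y1)
    return NO_CROSSING


def results_to_dataframe(results: list[ReplicateResult], **cell_keys) -> pd.DataFrame:
    """Tidy per-replicate table, one row per simulated study."""
    df = pd.DataFrame(
        {
            "replicate_index": [r.replicate_index for r in results],
            "measured_or": [r.measured_or for r in results],
            "p_value": [r.p_value for r in results],
            "realized_auroc": [r.realized_auroc for r in results],
            "deaths": [r.deaths for r in results],
            "treated": [r.treated for r in results],
            "conclusion": [r.conclusion for r in results],
            "converged": [r.converged for r in results],
        }
    )
    for k, v in cell_keys.items():
        df.insert(1, k, v)
    return df
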