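"""Confounding by indication: mapping baseline risk to treatment probability.

Treatment receipt is random but weighted by severity: the probability of
treatment follows a logistic curve in the log-odds of baseline risk,
logit(P(treated)) = a + b * logit(risk), with (a, b) solved exactly from two
printed anchor points. The built-in scenarios are

* ``none`` — treatment independent of risk at a constant marginal rate
  (default 0.45, the midpoint of the low-scenario anchors);
* ``low``  — risk 0.15 treated 30% of the time, risk 0.75 treated 60%
  (the sickest are about twice as likely to be treated);
* ``high`` — risk 0.15 treated 15% of the time, risk 0.75 treated 85%
  (the sickest are about five times as likely to be treated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import ValidationError
from .population import Cohort

__all__ = [
    "ConfoundingScenario",
    "calibrate_scenario",
    "assignment_probability",
    "assign_treatment",
    "LOW_ANCHORS",
    "HIGH_ANCHORS",
]

LOW_ANCHORS: tuple[tuple[float, float], ...] = ((0.15, 0.30), (0.75, 0.60))
HIGH_ANCHORS: tuple[tuple[float, float], ...] = ((0.15, 0.15), (0.75, 0.85))


@dataclass(frozen=True)
class ConfoundingScenario:
    """Risk-to-treatment-probability map for one confounding regime."""

    name: str
    intercept: float = 0.0
    slope: float = 0.0
    anchors: tuple = ()
    marginal_rate: float | None = None  # used only when slope == 0 and name == "none"

    @classmethod
    def none(cls, marginal_rate: float = 0.45) -> "ConfoundingScenario":
        """Unconfounded assignment at a constant marginal treatment rate."""
        if not 0 < marginal_rate < 1:
            raise ValidationError("marginal_rate must lie in (0, 1)")
        return cls(name="none", marginal_rate=marginal_rate)

    @classmethod
    def low(cls) -> "ConfoundingScenario":
        return calibrate_scenario(LOW_ANCHORS, name="low")

    @classmethod
    def high(cls) -> "ConfoundingScenario":
        return calibrate_scenario(HIGH_ANCHORS, name="high")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "slope": self.slope,
            "anchors": [list(a) for a in self.anchors],
            "marginal_rate": self.marginal_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfoundingScenario":
        return cls(
            name=d["name"],
            intercept=d.get("intercept", 0.0),
            slope=d.get("slope", 0.0),
            anchors=tuple(tuple(a) for a in d.get("anchors", ())),
            marginal_rate=d.get("marginal_rate"),
        )


def calibrate_scenario(anchors, name: str = "custom") -> ConfoundingScenario:
    """Solve the two-point calibration logit(p_k) = a + b * logit(risk_k).

    Two anchors give two linear equations in (a, b); the solution reproduces
    both anchor probabilities exactly.
    """
    anchors = tuple((float(r), float(p)) for r, p in anchors)
    if len(anchors) != 2:
        raise ValidationError("exactly two (risk, probability) anchors required")
    (r1, p1), (r2, p2) = anchors
    for v in (r1, r2, p1, p2):
        if not 0 < v < 1:
            raise ValidationError("anchor risks and probabilities must lie in (0, 1)")
    if r1 == r2:
        raise ValidationError("anchor risks must be distinct (singular system)")
    design = np.array([[1.0, special.logit(r1)], [1.0, special.logit(r2)]])
    a, b = np.linalg.solve(design, special.logit(np.array([p1, p2])))
    return ConfoundingScenario(
        name=name, intercept=float(a), slope=float(b), anchors=anchors
    )


def assignment_probability(scenario: ConfoundingScenario, risk):
    """Probability of receiving treatment at the given baseline risk(s)."""
    r = np.asarray(risk, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1):
        raise ValidationError("risk must lie strictly in (0, 1)")
    if scenario.name == "none":
        out = np.full_like(r, scenario.marginal_rate)
    else:
        out = special.expit(scenario.intercept + scenario.slope * special.logit(r))
    return float(out) if np.isscalar(risk) else out


def assign_treatment(
    cohort: Cohort, scenario: ConfoundingScenario, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli treatment draws with per-patient probabilities."""
    p = assignment_probability(scenario, cohort.baseline_risk)
    return (rng.random(cohort.n) < p).astype(np.int8)
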