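"""True treatment effect expressed as a constant odds ratio on mortality.

A treatment with odds ratio OR multiplies a patient's odds of death by OR:
p' = OR*p / (1 - p + OR*p). OR = 1 leaves risk unchanged (a safe treatment),
OR < 1 is beneficial, OR > 1 harmful. The transformation is exact, monotone in
both arguments, and maps the endpoints 0 and 1 to themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["TrueEffect", "apply_odds_ratio", "risk_difference"]


@dataclass(frozen=True)
class TrueEffect:
    """The treatment's true effect on the odds of death."""

    odds_ratio: float = 1.0

    def __post_init__(self):
        if not self.odds_ratio > 0:
            raise ValidationError(f"odds_ratio must be positive, got {self.odds_ratio}")


def apply_odds_ratio(risk, effect: TrueEffect | float):
    """Risk of death after treatment with the given odds ratio.

    Accepts a scalar or array of risks in [0, 1]; returns the same shape.
    """
    orr = effect.odds_ratio if isinstance(effect, TrueEffect) else float(effect)
    if not orr > 0:
        raise ValidationError(f"odds ratio must be positive, got {orr}")
    p = np.asarray(risk, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("risk must lie in [0, 1]")
    out = orr * p / (1.0 - p + orr * p)
    return float(out) if np.isscalar(risk) else out


def risk_difference(risk, effect: TrueEffect | float):
    """Absolute risk reduction: baseline risk minus post-treatment risk.

    Positive for a beneficial treatment (OR < 1).
    """
    p = np.asarray(risk, dtype=float)
    out = p - apply_odds_ratio(p, effect)
    return float(out) if np.isscalar(risk) else out
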