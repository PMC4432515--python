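"""Concordance statistic (AUROC) for a continuous score against a binary outcome.

The AUROC here is the Mann-Whitney concordance probability: the chance that a
randomly chosen death carries a higher score than a randomly chosen survivor,
with ties credited one half. Because the predicted probability from a
single-covariate logistic regression is a monotone transform of the covariate,
this equals the AUROC obtained by post-estimation after such a fit (when the
fitted slope is positive; a negative slope flips the orientation, which
:func:`empirical_auroc` handles explicitly).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedAUROCError

__all__ = ["empirical_auroc"]


def empirical_auroc(score, died) -> float:
    """Mann-Whitney concordance of ``score`` for predicting ``died``.

    Parameters
    ----------
    score
        Real-valued vector (higher = predicted more likely to die).
    died
        Binary vector of the same length (1 = died).

    Returns
    -------
    float
        P(score_death > score_survivor) + 0.5 * P(tie), computed from midranks
        in O(n log n).

    Raises
    ------
    UndefinedAUROCError
        If every outcome is identical (no death/survivor pairs exist).
    """
    score = np.asarray(score, dtype=float)
    died = np.asarray(died)
    if score.shape != died.shape or score.ndim != 1:
        raise ValueError("score and died must be 1-d vectors of equal length")
    died = died.astype(bool)
    n1 = int(died.sum())
    n0 = died.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUROCError(
            "AUROC undefined: only one outcome class present "
            f"(deaths={n1}, survivors={n0})"
        )
    ranks = rankdata(score)  # midranks handle ties
    u = ranks[died].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
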