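"""Counter-based random-number substreams.

One root seed drives an entire run; every (cell, replicate) pair gets its own
independent Generator derived from the root seed and an integer spawn key, so
any single replicate can be reproduced in isolation without replaying the ones
before it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return an independent Generator for the given root seed and spawn key.

    Parameters
    ----------
    seed
        Root seed of the run (non-negative integer).
    *key
        Zero or more non-negative integers identifying the substream, e.g.
        ``substream(seed, cell_index, replicate_index)``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if any(k < 0 for k in key):
        raise ValueError("spawn-key entries must be non-negative")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))
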