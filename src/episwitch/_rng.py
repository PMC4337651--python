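"""Seed handling.

Every stochastic operation in this package takes an explicit seed or an
already-constructed :class:`numpy.random.Generator`; there is no module-level
RNG state, so identical seeds always reproduce identical results.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ensure_rng", "spawn"]


def ensure_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    """Return a Generator from an explicit seed; refuse implicit seeding."""
    if seed is None:
        raise ValueError(
            "an explicit seed (int, SeedSequence, or Generator) is required; "
            "implicit global RNG state is not supported"
        )
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one seed."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seed.spawn(n)]
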