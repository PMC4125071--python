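"""Seed handling shared by every stochastic routine in the package."""
from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_generator(seed) -> np.random.Generator:
    """Return a PCG64 generator from an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one seed."""
    if isinstance(seed, np.random.Generator):
        return [np.random.default_rng(s) for s in seed.bit_generator.seed_seq.spawn(n)]
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
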