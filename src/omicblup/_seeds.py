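"""Deterministic seed derivation.

Every source of randomness in the package flows from a single master seed.
Child streams are derived with ``numpy.random.SeedSequence([master, *key])``
where ``key`` is a tuple of small non-negative integers naming the context
(e.g. the replicate index), so results are reproducible across runs and
platforms and independent streams never collide.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *key))
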