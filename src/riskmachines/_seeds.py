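"""Deterministic seed derivation.

A single master seed reproducibly spawns independent child seeds for
every stochastic component (data simulation, each forest fit, each
replicate of a study), so any individual piece of a run can be
re-executed in isolation.
"""

from __future__ import annotations

import numpy as np

# scikit-learn's random_state must fit in a signed 32-bit int
_SEED_MOD = 2**31


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning, so children are
    statistically independent and the mapping is stable across runs and
    platforms.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) % _SEED_MOD for child in ss.spawn(n)]


def spawn_rng(seed: int | None) -> np.random.Generator:
    """A fresh Generator from a (possibly None) seed."""
    return np.random.default_rng(seed)
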