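"""Seed plumbing: every source of randomness in the package derives from a
single master seed through named substreams."""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seed", "spawn_rng"]


def spawn_seed(master: int, *keys: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and a tuple of
    integer stream keys."""
    ss = np.random.SeedSequence(entropy=int(master) % (2 ** 63),
                                spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def spawn_rng(master: int, *keys: int) -> np.random.Generator:
    """numpy Generator seeded from the named substream."""
    return np.random.default_rng(spawn_seed(master, *keys))
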