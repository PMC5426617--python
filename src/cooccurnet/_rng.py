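"""Reproducible random-number plumbing.

Every stochastic operation in the package takes an integer master seed and
derives independent child generators through :class:`numpy.random.SeedSequence`
spawn keys, so replicate ``r`` of any Monte-Carlo loop can be re-run in
isolation and two runs with the same master seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_rng", "child_seed", "normalize_seed"]


def normalize_seed(seed) -> int:
    """Coerce ``seed`` to a plain non-negative int (None -> fresh entropy)."""
    if seed is None:
        return int(np.random.SeedSequence().entropy % (2**31))
    return int(seed)


def spawn_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible child generator for replicate ``key``."""
    ss = np.random.SeedSequence(
        entropy=normalize_seed(master_seed), spawn_key=tuple(int(k) for k in key)
    )
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *key: int) -> int:
    """A deterministic 31-bit integer sub-seed for replicate ``key``."""
    ss = np.random.SeedSequence(
        entropy=normalize_seed(master_seed), spawn_key=tuple(int(k) for k in key)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
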