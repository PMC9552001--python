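"""Deterministic seed derivation.

One master seed per run; every stochastic sub-stream (label assignment,
descriptor noise, fold shuffling per iteration, per-model randomness)
derives its own 31-bit seed from the master seed plus a fixed key path, so
reruns are byte-identical and streams never alias.
"""

from __future__ import annotations

import numpy as np


def derive_seed(master: int, *keys: int) -> int:
    """A reproducible 31-bit child seed for the sub-stream named by `keys`."""
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def derive_rng(master: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *keys))
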