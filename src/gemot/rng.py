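"""Seed derivation: one master seed fans out to independent child seeds.

Children are 31-bit non-negative integers so they stay portable across any
seed-taking interface.
"""

from __future__ import annotations

import numpy as np


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """n deterministic child seeds (int64, each < 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)
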