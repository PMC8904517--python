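"""Deterministic seed derivation for all stochastic stages."""

from __future__ import annotations

import numpy as np

_MOD = 2**31 - 1


def derive_seed(*parts: int) -> int:
    """Fold an arbitrary tuple of integers into a stable 31-bit seed.

    Uses numpy's SeedSequence so that nearby inputs produce uncorrelated
    streams; the result is safe to hand to sklearn's ``random_state``.
    """
    ss = np.random.SeedSequence([int(p) & 0xFFFFFFFF for p in parts])
    return int(ss.generate_state(1)[0]) % _MOD


def rng_for(*parts: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))
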