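"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (the convention used by the
    printed summary tables, which plain banker's rounding does not match)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def child_seed(seed: int, stream: int) -> int:
    """Derive a stable per-stage seed from one top-level seed.

    Uses SeedSequence spawning so reruns of an individual stage reproduce
    the full-pipeline stream. Result fits in 31 bits.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(stream,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
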