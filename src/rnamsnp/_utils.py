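"""Small shared helpers: rounding, RNG handling, formatting."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (half-up), as printed tables do.

    Python's built-in ``round`` is banker's rounding; summary tables in the
    GWAS literature round 0.125 -> 0.13, so we go through Decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int) -> float:
    """Percentage ``100 * count / total`` rounded half-up; 0.0 when total is 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, None, or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
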