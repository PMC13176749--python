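"""Small shared numeric helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report convention), not banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def sample_sd(values: Iterable[float]) -> float:
    """Sample standard deviation (n-1 denominator); 0.0 for a single value."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        return 0.0
    return float(np.std(arr, ddof=1))
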