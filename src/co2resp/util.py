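"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x, decimals: int = 0):
    """Round to `decimals` places with ties going away from zero.

    Publication tables in this field are typically produced by software
    that rounds half away from zero (e.g. 49.53 % displayed as 50); numpy's
    banker's rounding would disagree on exact ties, so rounding goes through
    :mod:`decimal`.
    """
    q = Decimal(10) ** -decimals
    if np.ndim(x) == 0:
        v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
        return v
    arr = np.asarray(x, dtype=float)
    out = np.empty(arr.shape, dtype=float)
    flat_in, flat_out = arr.ravel(), out.ravel()
    for i, v in enumerate(flat_in):
        flat_out[i] = float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))
    return out


def check_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name}: non-finite value encountered: {v!r}")
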