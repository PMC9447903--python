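"""Half-up rounding used for all reported (display) values.

Internally the pipeline keeps full double precision; rounding to the
precision of the printed cohort table happens only when a number is
reported.  Python's built-in ``round`` is banker's rounding, which does not
reproduce the printed values (6.5 must report as 7), hence this helper.
Rounding is half-away-from-zero applied to the shortest decimal
representation of the double, so 0.95*179 (= 170.049999...) reports as 170.
"""

from __future__ import annotations

import decimal

import numpy as np

__all__ = ["round_half_up"]


def _round_scalar(x: float, decimals: int) -> float:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    q = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def round_half_up(x, decimals: int = 0):
    """Round half away from zero at ``decimals`` decimal places.

    Accepts scalars or array-likes; returns a float scalar or float ndarray.
    NaN passes through (missing cells stay missing).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return _round_scalar(float(arr), decimals)
    out = np.array([_round_scalar(v, decimals) for v in arr.ravel()])
    return out.reshape(arr.shape)
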