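"""Colony-counting error metrics: MAE and sMAPE."""

from __future__ import annotations

import numpy as np

from .datamodel import ValidationError


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValidationError("metrics require at least one (predicted, true) pair")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"expected an (n, 2) array of count pairs, got {arr.shape}")
    if (arr < 0).any():
        raise ValidationError("counts must be nonnegative")
    return arr


def mae(pairs) -> float:
    """Mean absolute error between predicted and true counts."""
    arr = _as_pairs(pairs)
    return float(np.abs(arr[:, 0] - arr[:, 1]).mean())


def smape(pairs) -> float:
    """Symmetric mean absolute percentage error, in percent.

    Per-pair term: |p - t| / ((p + t) / 2), defined as 0 when both counts are
    zero; the mean is scaled by 100.  Ranges over [0, 200].  The symmetric
    (p + t)/2 denominator is the standard form; it weights errors by how
    populated the dish is.
    """
    arr = _as_pairs(pairs)
    p, t = arr[:, 0], arr[:, 1]
    denom = (p + t) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, np.abs(p - t) / denom, 0.0)
    return float(100.0 * terms.mean())


__all__ = ["mae", "smape"]
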