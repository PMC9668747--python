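"""Small numeric helpers shared across modules (circular-track geometry)."""

from __future__ import annotations

import numpy as np


def circular_distance(a, b, length: float = 180.0):
    """Unsigned distance between track positions on a loop of given length."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % length
    return np.minimum(d, length - d)


def circular_signed_difference(a, b, length: float = 180.0):
    """Signed difference a - b wrapped into (-length/2, length/2].

    Negative values point opposite to the running direction (backward).
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % length
    return np.where(d > length / 2.0, d - length, d)


def circular_boxcar(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Three-point boxcar smoothing with wrap-around (the belt is a loop)."""
    x = np.asarray(x, dtype=float)
    return (np.roll(x, 1, axis=axis) + x + np.roll(x, -1, axis=axis)) / 3.0


def circular_interpolate_nan(values: np.ndarray) -> np.ndarray:
    """Fill NaN entries of a 1-D circular profile by linear interpolation
    from the nearest valid neighbours on either side."""
    v = np.asarray(values, dtype=float).copy()
    n = v.size
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad.all():
        raise ValueError("cannot interpolate: no finite bins")
    good = np.flatnonzero(~bad)
    # unwrap onto a tripled axis so np.interp sees both circular neighbours
    xg = np.concatenate([good - n, good, good + n])
    yg = np.tile(v[good], 3)
    v[bad] = np.interp(np.flatnonzero(bad), xg, yg)
    return v


def pearson(x, y) -> float:
    """Pearson correlation returning NaN (not an error) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
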