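"""Moving-window ordinary-least-squares helpers shared by the fitters."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sliding_ols(x: np.ndarray, y: np.ndarray, window: int):
    """Per-window OLS of y on x with a stride-1 moving window.

    Returns (slope, r2, x_center, valid) arrays of length n - window + 1.
    ``x_center`` is the mean of x in each window. Windows containing any
    non-finite y are marked invalid (slope/r2 NaN) rather than clipped,
    so noise-floor samples cannot bias the fit. For windows where y is
    exactly constant the slope is 0 and r2 is reported as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < window:
        raise ValueError(f"need at least {window} samples, got {n}")

    wx = sliding_window_view(x, window)
    wy = sliding_window_view(y, window)
    valid = np.isfinite(wy).all(axis=1)

    xm = wx.mean(axis=1)
    wy_safe = np.where(np.isfinite(wy), wy, 0.0)
    ym = wy_safe.mean(axis=1)
    dx = wx - xm[:, None]
    dy = wy_safe - ym[:, None]
    sxx = np.einsum("ij,ij->i", dx, dx)
    sxy = np.einsum("ij,ij->i", dx, dy)
    syy = np.einsum("ij,ij->i", dy, dy)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 1.0)
    slope = np.where(valid, slope, np.nan)
    r2 = np.where(valid, r2, np.nan)
    return slope, r2, xm, valid


def window_centers(values: np.ndarray, window: int) -> np.ndarray:
    """Per-window means of an auxiliary axis (e.g. strain) for stride-1 windows."""
    v = np.asarray(values, dtype=float)
    return sliding_window_view(v, window).mean(axis=1)
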