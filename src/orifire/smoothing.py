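"""Tricube-weighted local linear (LOESS) smoothing with a fixed bandwidth
in base pairs.

Both the marker-frequency pipeline (50 kb window on 1 kb bins) and the
ssDNA pipeline (6 or 9 kb window, evaluated on a 0.25 kb grid) smooth
genomic signals with a window expressed as a physical width, not a
fraction of the data.  ``window_bp`` is the FULL window width: tricube
weights fall to zero at ``± window_bp / 2`` from the evaluation point.

At each evaluation point x0 the fit solves the weighted least-squares
problem  min Σ w_i (y_i − a − b (x_i − x0))²  with
w_i = (1 − |(x_i − x0)/h|³)³, h = window_bp/2, and returns a (the local
intercept).  NaN observations are excluded from each local fit; the output
is NaN wherever fewer than ``min_points`` finite observations carry
positive weight.  A constant input is reproduced exactly and an exactly
linear input is reproduced to numerical precision, because the local model
contains both.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_points"]


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel on |u| < 1, zero outside."""
    au = np.abs(u)
    w = (1.0 - au**3) ** 3
    w[au >= 1.0] = 0.0
    return w


def loess_points(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    window_bp: float,
    min_points: int = 3,
) -> np.ndarray:
    """Evaluate the tricube local linear fit of (x, y) at ``x_eval``.

    ``x`` must be sorted ascending.  Returns an array of ``len(x_eval)``
    with NaN where the local fit is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    finite = np.isfinite(y)
    xf = x[finite]
    yf = y[finite]
    out = np.full(len(x_eval), np.nan)
    if len(xf) == 0:
        return out

    half = window_bp / 2.0
    lo = np.searchsorted(xf, x_eval - half, side="left")
    hi = np.searchsorted(xf, x_eval + half, side="right")

    for i, x0 in enumerate(x_eval):
        a, b = lo[i], hi[i]
        if b - a < min_points:
            continue
        xs = xf[a:b] - x0
        w = tricube(xs / half)
        pos = w > 0
        if pos.sum() < min_points:
            continue
        xs = xs[pos]
        ys = yf[a:b][pos]
        w = w[pos]
        sw = w.sum()
        swx = np.dot(w, xs)
        swy = np.dot(w, ys)
        swxx = np.dot(w, xs * xs)
        swxy = np.dot(w, xs * ys)
        denom = sw * swxx - swx * swx
        if denom <= 1e-12 * max(sw * swxx, 1e-300):
            # degenerate design (e.g. all points at one x): weighted mean
            out[i] = swy / sw
        else:
            out[i] = (swxx * swy - swx * swxy) / denom
    return out
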