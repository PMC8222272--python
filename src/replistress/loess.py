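"""Tricube-weighted local-linear (loess) regression with pointwise standard errors.

This is the numerical core shared by the MA-plot dye-bias normalization
(nearest-neighbour span, fraction of points) and the genomic RT smoothing
(fixed base-pair bandwidth).  At every evaluation point x0 a degree-1
weighted least-squares fit is solved in closed form over the window of
points with tricube weight

    w_i = (1 - (|x_i - x0| / h)^3)^3     for |x_i - x0| < h, else 0.

The fitted value is a linear functional of the responses, fit = l(x0)'y,
so its standard error under homoscedastic residuals is sigma * ||l(x0)||.
sigma is estimated globally from the residuals of the fit with the usual
degrees-of-freedom correction df = n - trace(L).

Windows with fewer than ``min_points`` probes (or a degenerate design) give
NaN fit/SE ("missing" probes).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

__all__ = ["LoessResult", "local_linear_fit"]


@dataclass
class LoessResult:
    """Fit of y on x at every input point."""

    fitted: np.ndarray  # fitted values, NaN where the local fit is degenerate
    se: np.ndarray  # standard error of the fitted value, NaN where missing
    sigma: float  # global residual standard deviation estimate
    l2norm: np.ndarray  # ||l(x_i)|| of the equivalent-kernel weight vector
    leverage: np.ndarray  # diagonal of the smoother matrix
    df_model: float  # trace of the smoother matrix

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.fitted)


def _knn_halfwidths(x: np.ndarray, k: int) -> np.ndarray:
    """Distance from each x_i to its k-th nearest neighbour (x sorted)."""
    n = x.size
    k = min(k, n)
    h = np.empty(n)
    for i in range(n):
        lo_min = max(0, i - k + 1)
        lo_max = min(i, n - k)
        # span(j) = max(x[i]-x[j], x[j+k-1]-x[i]); left term decreasing in j,
        # right term increasing -> minimize by bisection on their crossing.
        lo, hi = lo_min, lo_max
        while lo < hi:
            mid = (lo + hi) // 2
            if x[i] - x[mid] > x[mid + k - 1] - x[i]:
                lo = mid + 1
            else:
                hi = mid
        best = max(x[i] - x[lo], x[lo + k - 1] - x[i])
        if lo > lo_min:
            alt = max(x[i] - x[lo - 1], x[lo + k - 2] - x[i])
            best = min(best, alt)
        h[i] = best
    return h


def local_linear_fit(
    x: np.ndarray,
    y: np.ndarray,
    *,
    bandwidth: float | None = None,
    frac: float | None = None,
    min_points: int = 3,
    chunk: int = 128,
) -> LoessResult:
    """Local-linear tricube regression of ``y`` on ``x`` evaluated at every ``x``.

    Exactly one of ``bandwidth`` (kernel half-width in x units; the window at
    x0 is ``(x0 - bandwidth, x0 + bandwidth)``) or ``frac`` (nearest-neighbour
    span as a fraction of points, classical loess) must be given.

    ``x`` need not be sorted; results are returned in the input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if (bandwidth is None) == (frac is None):
        raise ValueError("specify exactly one of bandwidth or frac")
    n = x.size
    if n < min_points:
        raise ValueError(f"need at least {min_points} points, got {n}")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]

    if bandwidth is not None:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        h = np.full(n, float(bandwidth))
        lo = np.searchsorted(xs, xs - bandwidth, side="left")
        hi = np.searchsorted(xs, xs + bandwidth, side="right")
    else:
        if not 0 < frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        k = max(int(np.ceil(frac * n)), min_points + 1)
        k = min(k, n)
        h = _knn_halfwidths(xs, k)
        h = np.maximum(h, np.finfo(float).tiny)
        lo = np.searchsorted(xs, xs - h, side="left")
        hi = np.searchsorted(xs, xs + h, side="right")

    fitted = np.full(n, np.nan)
    l2 = np.full(n, np.nan)
    lev = np.zeros(n)

    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        rows = np.arange(c0, c1)
        wmax = int(np.max(hi[rows] - lo[rows]))
        idx = lo[rows, None] + np.arange(wmax)[None, :]
        valid = idx < hi[rows, None]
        idx = np.minimum(idx, n - 1)
        d = xs[idx] - xs[rows, None]
        u = np.abs(d) / h[rows, None]
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        w[~valid] = 0.0
        yy = ys[idx]

        sw = w.sum(axis=1)
        s1 = (w * d).sum(axis=1)
        s2 = (w * d * d).sum(axis=1)
        t0 = (w * yy).sum(axis=1)
        t1 = (w * d * yy).sum(axis=1)
        det = sw * s2 - s1 * s1
        npts = (w > 0).sum(axis=1)
        scale = sw * s2 + s1 * s1
        ok = (npts >= min_points) & (det > 1e-12 * np.maximum(scale, np.finfo(float).tiny))

        with np.errstate(invalid="ignore", divide="ignore"):
            lw = w * (s2[:, None] - s1[:, None] * d) / det[:, None]
        fit_c = np.where(ok, (s2 * t0 - s1 * t1) / np.where(det == 0, np.nan, det), np.nan)
        l2_c = np.where(ok, (lw * lw).sum(axis=1), np.nan)
        center_col = rows - lo[rows]
        lev_c = np.where(ok, lw[np.arange(rows.size), center_col], 0.0)

        fitted[rows] = fit_c
        l2[rows] = l2_c
        lev[rows] = lev_c

    good = np.isfinite(fitted)
    resid = ys[good] - fitted[good]
    trace = float(lev[good].sum())
    df = max(good.sum() - trace, 1.0)
    sigma = float(np.sqrt((resid**2).sum() / df)) if good.any() else float("nan")

    l2norm = np.sqrt(l2)
    se = sigma * l2norm

    inv = np.empty(n, dtype=np.intp)
    inv[order] = np.arange(n)
    return LoessResult(
        fitted=fitted[inv],
        se=se[inv],
        sigma=sigma,
        l2norm=l2norm[inv],
        leverage=lev[inv],
        df_model=trace,
    )
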