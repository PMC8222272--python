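"""Two-channel array normalization for replication-timing profiles.

Raw arrays carry, per probe, an early-S and a late-S channel intensity.
They are reduced to MA coordinates (M = log2 early/late, the RT log-ratio;
A = mean log2 intensity), de-biased within each array by a loess fit of M on
A (intensity-dependent dye bias), and made comparable between arrays by
quantile normalization of the M-values.  A positive M means the probe
replicates early, a negative M late.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import GenomeLayout
from .loess import local_linear_fit

__all__ = [
    "RTArray",
    "ma_transform",
    "MALoessNormalizer",
    "loess_normalize_within",
    "QuantileNormalizer",
    "quantile_normalize_between",
]


@dataclass
class RTArray:
    """Per-probe M/A values for one sample-replicate on a genome layout."""

    M: np.ndarray
    A: np.ndarray | None = None
    layout: GenomeLayout | None = None
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.A is not None:
            self.A = np.asarray(self.A, dtype=float)
            if self.A.shape != self.M.shape:
                raise ValueError("M and A must have the same length")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M values must be finite")
        if self.layout is not None and self.M.size != self.layout.n_probes:
            raise ValueError(
                f"array has {self.M.size} probes but layout has {self.layout.n_probes}"
            )

    @property
    def label(self) -> str:
        return f"{self.condition}:rep{self.replicate}"


def ma_transform(
    early_intensity: np.ndarray, late_intensity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MA coordinates from raw channel intensities.

    M = log2(early/late), A = (log2 early + log2 late) / 2.  Raises on any
    non-positive intensity, naming the offending probe index.
    """
    early = np.asarray(early_intensity, dtype=float)
    late = np.asarray(late_intensity, dtype=float)
    if early.shape != late.shape:
        raise ValueError("channel vectors must have equal length")
    for name, v in (("early", early), ("late", late)):
        bad = np.flatnonzero(~(v > 0))
        if bad.size:
            raise ValueError(
                f"non-positive {name}-channel intensity at probe index {int(bad[0])}"
            )
    le = np.log2(early)
    ll = np.log2(late)
    return le - ll, (le + ll) / 2.0


class MALoessNormalizer(BaseEstimator):
    """Intensity-dependent bias trend f(A) fitted by loess, removed from M.

    A degree-1 tricube local regression of M on A with a nearest-neighbour
    span of ``span`` (fraction of probes) estimates the dye-bias curve;
    normalized values are the residuals M - f(A).
    """

    def __init__(self, span: float = 0.3, min_probes: int = 50):
        self.span = span
        self.min_probes = min_probes

    def fit(self, X, y):
        """Fit the trend of y (M) on X (A values, shape (n,) or (n, 1))."""
        A = np.asarray(X, dtype=float).reshape(-1)
        M = np.asarray(y, dtype=float).reshape(-1)
        if A.size != M.size:
            raise ValueError("A and M must have the same length")
        if A.size < self.min_probes:
            raise ValueError(
                f"need at least {self.min_probes} probes for MA loess, got {A.size}"
            )
        res = local_linear_fit(A, M, frac=self.span)
        self.trend_ = res.fitted
        self.residual_ = M - res.fitted
        order = np.argsort(A, kind="stable")
        self._knots_a = A[order]
        self._knots_f = res.fitted[order]
        return self

    def predict(self, X):
        """Trend value at new A coordinates (interpolated between fitted probes)."""
        A = np.asarray(X, dtype=float).reshape(-1)
        good = np.isfinite(self._knots_f)
        return np.interp(A, self._knots_a[good], self._knots_f[good])


def loess_normalize_within(M, A, span_points: float = 0.3) -> np.ndarray:
    """Within-array normalization: M minus the loess trend of M on A."""
    return MALoessNormalizer(span=span_points).fit(A, M).residual_


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization across arrays (columns of X).

    The reference distribution is the per-rank mean of the column order
    statistics; every column is mapped onto it rank-for-rank, so all
    normalized columns share identical sorted values while preserving each
    column's internal ordering.  Tied values receive the mean of the
    reference quantiles their ranks span, making the map stable under
    permutation of equal entries.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n_probes, n_arrays) with >= 2 arrays")
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        self.n_probes_ = X.shape[0]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        if X.shape[0] != self.n_probes_:
            raise ValueError(
                f"array length {X.shape[0]} does not match fitted length {self.n_probes_}"
            )
        out = np.empty_like(X)
        ref = self.reference_
        for j in range(X.shape[1]):
            col = X[:, j]
            order = np.argsort(col, kind="stable")
            mapped = np.empty_like(ref)
            mapped[order] = ref
            _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
            if np.any(counts > 1):  # ties -> mean of spanned quantiles
                sums = np.bincount(inverse, weights=mapped)
                mapped = (sums / counts)[inverse]
            out[:, j] = mapped
        return out[:, 0] if squeeze else out


def quantile_normalize_between(arrays: list[np.ndarray]) -> list[np.ndarray]:
    """Quantile-normalize a list of equal-length M vectors against each other."""
    if len(arrays) < 2:
        raise ValueError("need at least 2 arrays")
    lengths = {np.asarray(a).shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"arrays have mismatched lengths: {sorted(lengths)}")
    X = np.column_stack([np.asarray(a, dtype=float) for a in arrays])
    Xn = QuantileNormalizer().fit_transform(X)
    return [Xn[:, j] for j in range(Xn.shape[1])]
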