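"""Smoothed replication-timing profiles and CI-based differential calling.

The normalized per-probe RT log-ratios of each chromosome are smoothed by a
local-linear tricube regression over a fixed base-pair window (3 Mb full
width by default, i.e. a kernel half-width of 1.5 Mb).  Replicate profiles
are averaged probe-wise, and a confidence band fit ± z(level)·SE is attached
to the loess refit of the averaged signal.  A probe is differentially timed
between two conditions when the two confidence intervals are disjoint;
maximal same-direction runs of at least ``min_probes`` such probes become
regions, called *earlier* when the condition of interest sits above the
reference (higher RT log-ratio = earlier replication) and *later* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .genome import GenomeLayout
from .loess import local_linear_fit
from .normalize import RTArray

__all__ = [
    "SmoothedRTProfile",
    "DifferentialRegion",
    "LoessSmoother",
    "loess_smooth",
    "smooth_array",
    "average_replicates",
    "profile_ci",
    "call_differential",
    "genome_fraction",
]

DEFAULT_BANDWIDTH_BP = 3_000_000  # full window width
DEFAULT_CI_LEVEL = 0.95
DEFAULT_MIN_PROBES = 8


@dataclass
class SmoothedRTProfile:
    """Per-probe loess fit with standard errors and confidence bounds."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    position: np.ndarray
    fit: np.ndarray
    se: np.ndarray
    level: float
    lower: np.ndarray
    upper: np.ndarray
    condition: str = ""
    layout: GenomeLayout | None = None

    def __post_init__(self) -> None:
        n = self.fit.size
        for name in ("chrom", "start", "end", "position", "se", "lower", "upper"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name} length mismatch")
        ok = np.isfinite(self.fit)
        if np.any(self.se[ok] < 0):
            raise ValueError("negative standard error")
        if np.any(self.lower[ok] > self.fit[ok]) or np.any(self.fit[ok] > self.upper[ok]):
            raise ValueError("confidence bounds must bracket the fit")

    @property
    def n_probes(self) -> int:
        return int(self.fit.size)

    def same_grid(self, other: "SmoothedRTProfile") -> bool:
        return (
            self.n_probes == other.n_probes
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "fit": self.fit,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass(frozen=True)
class DifferentialRegion:
    """Genomic interval replicating earlier or later than the reference."""

    chrom: str
    start: int
    end: int
    direction: str  # "earlier" | "later"
    mean_delta: float  # condition fit - reference fit, log2 units
    n_probes: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")
        if self.direction not in ("earlier", "later"):
            raise ValueError(f"bad direction {self.direction!r}")
        if (self.direction == "earlier") != (self.mean_delta > 0):
            raise ValueError("direction inconsistent with sign of mean_delta")

    @property
    def length(self) -> int:
        return self.end - self.start


class LoessSmoother(BaseEstimator):
    """Genomic loess smoother: local-linear tricube fit over a bp window.

    Parameters
    ----------
    bandwidth
        Full window width in bp; probes within +- bandwidth/2 of the target
        probe contribute to its fit.
    level
        Confidence level for the band fit +- z(level) * SE.
    """

    def __init__(self, bandwidth: float = DEFAULT_BANDWIDTH_BP, level: float = DEFAULT_CI_LEVEL):
        self.bandwidth = bandwidth
        self.level = level

    def fit(self, X, y):
        """Fit M values (y) against probe positions (X, shape (n,) or (n,1))."""
        positions = np.asarray(X, dtype=float).reshape(-1)
        M = np.asarray(y, dtype=float).reshape(-1)
        if positions.size != M.size:
            raise ValueError("positions and M must have equal length")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        spacing = np.min(np.diff(positions)) if positions.size > 1 else 0.0
        if self.bandwidth <= spacing:
            raise ValueError("bandwidth must exceed the probe spacing")
        res = local_linear_fit(positions, M, bandwidth=self.bandwidth / 2.0)
        z = norm.ppf(0.5 + self.level / 2.0)
        self.positions_ = positions
        self.fitted_ = res.fitted
        self.se_ = res.se
        self.sigma_ = res.sigma
        self.lower_ = res.fitted - z * res.se
        self.upper_ = res.fitted + z * res.se
        return self

    def predict(self, X):
        """Fitted values at new positions, linearly interpolated between probes."""
        pos = np.asarray(X, dtype=float).reshape(-1)
        good = np.isfinite(self.fitted_)
        return np.interp(pos, self.positions_[good], self.fitted_[good])


def loess_smooth(
    M,
    positions,
    bandwidth: float = DEFAULT_BANDWIDTH_BP,
    *,
    level: float = DEFAULT_CI_LEVEL,
    chrom: str = "chr1",
    spacing: int | None = None,
    condition: str = "",
) -> SmoothedRTProfile:
    """Smooth one chromosome's M vector; see :class:`LoessSmoother`."""
    sm = LoessSmoother(bandwidth=bandwidth, level=level).fit(positions, M)
    pos = sm.positions_
    if spacing is None:
        spacing = int(np.min(np.diff(pos))) if pos.size > 1 else 1
    start = (pos - spacing).astype(np.int64)
    return SmoothedRTProfile(
        chrom=np.repeat(np.asarray([chrom], dtype=object), pos.size),
        start=start,
        end=pos.astype(np.int64),
        position=pos,
        fit=sm.fitted_,
        se=sm.se_,
        level=level,
        lower=sm.lower_,
        upper=sm.upper_,
        condition=condition,
    )


def _smooth_layout(
    M: np.ndarray,
    layout: GenomeLayout,
    bandwidth: float,
    level: float,
    condition: str,
) -> SmoothedRTProfile:
    """Per-chromosome smoothing of a genome-wide M vector on a layout grid."""
    probes = layout.probes
    n = layout.n_probes
    if M.size != n:
        raise ValueError("M length does not match layout")
    fit = np.full(n, np.nan)
    se = np.full(n, np.nan)
    z = norm.ppf(0.5 + level / 2.0)
    for chrom_name, sl in layout.chrom_slices().items():
        k = sl.stop - sl.start
        if k == 0:
            continue
        pos = probes["position"].to_numpy()[sl].astype(float)
        if k < 3:
            continue  # too few probes: left missing
        res = local_linear_fit(pos, M[sl], bandwidth=bandwidth / 2.0)
        fit[sl] = res.fitted
        se[sl] = res.se
    return SmoothedRTProfile(
        chrom=probes["chrom"].to_numpy(),
        start=probes["start"].to_numpy(),
        end=probes["end"].to_numpy(),
        position=probes["position"].to_numpy().astype(float),
        fit=fit,
        se=se,
        level=level,
        lower=fit - z * se,
        upper=fit + z * se,
        condition=condition,
    )


def smooth_array(
    array: RTArray,
    bandwidth: float = DEFAULT_BANDWIDTH_BP,
    level: float = DEFAULT_CI_LEVEL,
) -> SmoothedRTProfile:
    """Smooth a normalized array per chromosome on its layout grid."""
    if array.layout is None:
        raise ValueError("array must carry a layout")
    prof = _smooth_layout(array.M, array.layout, bandwidth, level, array.condition)
    prof.layout = array.layout
    return prof


def average_replicates(profiles: list[SmoothedRTProfile]) -> np.ndarray:
    """Probe-wise arithmetic mean of replicate fits (same grid, same condition)."""
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if not first.same_grid(p):
            raise ValueError("replicate profiles are on different probe grids")
        if p.condition != first.condition:
            raise ValueError(
                f"mixed conditions: {first.condition!r} vs {p.condition!r}"
            )
    return np.mean([p.fit for p in profiles], axis=0)


def profile_ci(
    averaged,
    positions=None,
    bandwidth: float = DEFAULT_BANDWIDTH_BP,
    level: float = DEFAULT_CI_LEVEL,
    *,
    layout: GenomeLayout | None = None,
    condition: str = "",
) -> SmoothedRTProfile:
    """Loess refit of an averaged profile with a ``level`` confidence band.

    Either ``positions`` (single chromosome) or ``layout`` (genome-wide,
    smoothed per chromosome) must be provided.
    """
    averaged = np.asarray(averaged, dtype=float)
    if layout is not None:
        prof = _smooth_layout(averaged, layout, bandwidth, level, condition)
        prof.layout = layout
        return prof
    if positions is None:
        raise ValueError("provide positions or a layout")
    return loess_smooth(
        averaged, positions, bandwidth, level=level, condition=condition
    )


def call_differential(
    cond: SmoothedRTProfile,
    ref: SmoothedRTProfile,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> list[DifferentialRegion]:
    """Differential-RT regions where the two confidence bands do not intersect.

    A probe is differential iff [cond.lower, cond.upper] and
    [ref.lower, ref.upper] are disjoint; maximal same-direction runs of at
    least ``min_probes`` differential probes become regions spanning from the
    first probe's start to the last probe's end.
    """
    if not cond.same_grid(ref):
        raise ValueError("condition and reference profiles are on different grids")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    finite = (
        np.isfinite(cond.lower)
        & np.isfinite(cond.upper)
        & np.isfinite(ref.lower)
        & np.isfinite(ref.upper)
    )
    disjoint = finite & ((cond.lower > ref.upper) | (cond.upper < ref.lower))
    earlier = disjoint & (cond.fit > ref.fit)
    # state: 0 = not differential, +1 earlier, -1 later
    state = np.where(disjoint, np.where(earlier, 1, -1), 0)

    regions: list[DifferentialRegion] = []
    n = state.size
    i = 0
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and state[j + 1] == state[i]
            and cond.chrom[j + 1] == cond.chrom[i]
        ):
            j += 1
        run = slice(i, j + 1)
        if (j - i + 1) >= min_probes:
            delta = float(np.mean(cond.fit[run] - ref.fit[run]))
            regions.append(
                DifferentialRegion(
                    chrom=str(cond.chrom[i]),
                    start=int(cond.start[i]),
                    end=int(cond.end[j]),
                    direction="earlier" if state[i] > 0 else "later",
                    mean_delta=delta,
                    n_probes=j - i + 1,
                )
            )
        i = j + 1
    return regions


def genome_fraction(
    regions: list[DifferentialRegion],
    layout: GenomeLayout,
    per_chromosome: bool = False,
) -> pd.DataFrame:
    """Percent of the probe-covered genome (or chromosome) in differential regions.

    The covered length of a chromosome is the span from its first probe start
    to its last probe end.  Returns a tidy table (scope, direction, percent).
    """
    covered = layout.covered_length
    for r in regions:
        if r.chrom not in covered:
            raise ValueError(f"region on unknown chromosome {r.chrom!r}")
        if r.end > covered[r.chrom]:
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} outside probe-covered span"
            )
    total = sum(covered.values())
    rows = []

    def add_scope(scope: str, length: int, rs: list[DifferentialRegion]) -> None:
        for direction in ("earlier", "later"):
            rl = sum(r.length for r in rs if r.direction == direction)
            pct = 100.0 * rl / length if length > 0 else 0.0
            rows.append({"scope": scope, "direction": direction, "percent": pct})

    add_scope("genome", total, regions)
    if per_chromosome:
        for name in layout.chrom_names:
            add_scope(name, covered[name], [r for r in regions if r.chrom == name])
    return pd.DataFrame(rows)
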