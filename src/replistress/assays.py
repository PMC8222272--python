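"""Telomere and growth assay quantifications.

Covers population-doubling arithmetic, TRF (terminal restriction fragment)
Southern-blot quantification with ladder calibration, telomere shortening
rates, qPCR fold enrichment, MadID m6A dot-blot normalization, and ChIP
enrichment ratios.

The TRF mean uses the optical-density-weighted harmonic correction

    mean length = sum_i OD_i / sum_i (OD_i / L_i)

which compensates for longer restriction fragments binding proportionally
more probe, the standard correction for telomere smears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TRFLane",
    "DotBlotMeasurement",
    "LadderCalibration",
    "population_doublings",
    "cumulative_population_doublings",
    "calibrate_ladder",
    "trf_mean_length",
    "shortening_rate",
    "qpcr_fold_enrichment",
    "madid_normalized_m6a",
    "chip_enrichment",
    "normalized_lane_profile",
]


@dataclass
class TRFLane:
    """One Southern-blot lane: smear intensity as a function of gel distance."""

    distance: np.ndarray
    intensity: np.ndarray
    pd_at_sampling: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance.shape != self.intensity.shape:
            raise ValueError("distance and intensity must have equal length")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("gel distances must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class DotBlotMeasurement:
    """One MadID dot-blot replicate: m6A signal and telomere quantity by qPCR."""

    condition: str
    m6a_intensity: float
    telomere_qpcr: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.m6a_intensity <= 0 or self.telomere_qpcr <= 0:
            raise ValueError("measurements must be > 0")


def population_doublings(c1: float, c2: float) -> float:
    """PD = log2(C2 / C1): harvested over seeded cell counts."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("cell counts must be > 0")
    return float(np.log2(c2 / c1))


def cumulative_population_doublings(passages: list[tuple[float, float]]) -> list[float]:
    """Running cumulative PD across successive (seeded, harvested) passages."""
    pds = [population_doublings(c1, c2) for c1, c2 in passages]
    return list(np.cumsum(pds))


class LadderCalibration:
    """Monotone gel-distance <-> fragment-size map from ladder band positions.

    Interpolates log(kb) against migration distance with a monotone cubic
    (PCHIP), exact at the calibration knots, with an inverse map.
    """

    def __init__(self, distances: np.ndarray, kb: np.ndarray):
        distances = np.asarray(distances, dtype=float)
        kb = np.asarray(kb, dtype=float)
        if distances.size < 3:
            raise ValueError("need at least 3 calibration points")
        order = np.argsort(distances)
        distances, kb = distances[order], kb[order]
        if np.any(np.diff(distances) <= 0):
            raise ValueError("duplicate ladder distances")
        if np.any(kb <= 0):
            raise ValueError("ladder sizes must be > 0")
        if np.any(np.diff(kb) >= 0):
            raise ValueError("ladder must be monotone: kb decreasing with distance")
        self.distances = distances
        self.kb = kb
        self._fwd = PchipInterpolator(distances, np.log(kb), extrapolate=True)
        self._inv = PchipInterpolator(np.log(kb[::-1]), distances[::-1], extrapolate=True)

    def __call__(self, distance):
        out = np.exp(self._fwd(np.asarray(distance, dtype=float)))
        return float(out) if out.ndim == 0 else out

    def inverse(self, kb):
        out = self._inv(np.log(np.asarray(kb, dtype=float)))
        return float(out) if out.ndim == 0 else out


def calibrate_ladder(points: list[tuple[float, float]]) -> LadderCalibration:
    """Build a distance->kb calibration from (distance, kb) ladder bands."""
    pts = np.asarray(points, dtype=float)
    return LadderCalibration(pts[:, 0], pts[:, 1])


def trf_mean_length(lane: TRFLane, ladder_map: LadderCalibration) -> float:
    """OD-weighted mean telomere length (kb) of a TRF smear.

    mean = sum(OD) / sum(OD / L) over profile bins, with L from the ladder.
    """
    od = lane.intensity
    total = float(od.sum())
    if total <= 0:
        raise ValueError("lane has zero total intensity")
    lengths = ladder_map(lane.distance)
    return total / float((od / lengths).sum())


def shortening_rate(lengths_kb, pds) -> float:
    """Telomere shortening rate in bp/PD: minus the OLS slope of length on PD."""
    lengths_bp = np.asarray(lengths_kb, dtype=float) * 1000.0
    pds = np.asarray(pds, dtype=float)
    if lengths_bp.shape != pds.shape or pds.size < 2:
        raise ValueError("need matching length/PD vectors with >= 2 samples")
    if np.ptp(pds) == 0:
        raise ValueError("all PDs identical; slope undefined")
    slope = np.polyfit(pds, lengths_bp, 1)[0]
    return float(-slope)


def qpcr_fold_enrichment(ct_sample, ct_reference, efficiency: float = 2.0):
    """Fold enrichment = efficiency ** (Ct_reference - Ct_sample).

    Default efficiency 2.0 (amplification close to 100% per the telomere
    qPCR control).
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    ct_sample = np.asarray(ct_sample, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_sample)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("Ct values must be finite")
    out = efficiency ** (ct_reference - ct_sample)
    return float(out) if out.ndim == 0 else out


def madid_normalized_m6a(
    measurements: list[DotBlotMeasurement] | pd.DataFrame,
    reference_condition: str,
) -> pd.DataFrame:
    """Telomere-normalized m6A signal relative to a reference condition.

    Per replicate r = m6A / telomere quantity; per condition the replicate
    mean of r is divided by the reference mean, so the reference maps to 1.0
    and all outputs are gain-invariant.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame(
            {
                "condition": [m.condition for m in measurements],
                "m6a_intensity": [m.m6a_intensity for m in measurements],
                "telomere_qpcr": [m.telomere_qpcr for m in measurements],
            }
        )
    if (df[["m6a_intensity", "telomere_qpcr"]] <= 0).any(axis=None):
        raise ValueError("measurements must be > 0")
    df["ratio"] = df["m6a_intensity"] / df["telomere_qpcr"]
    means = df.groupby("condition", sort=False)["ratio"].mean()
    if reference_condition not in means.index:
        raise ValueError(f"reference condition {reference_condition!r} not present")
    rel = means / means[reference_condition]
    return rel.rename("relative_normalized_m6a").reset_index()


def chip_enrichment(
    ip_signal,
    input_signal,
    h3_signal=None,
    input_fraction: float = 1.0,
) -> tuple[float | np.ndarray, float | np.ndarray | None]:
    """ChIP enrichment relative to input and, optionally, to H3.

    vs_input = IP / (input scaled to full material); vs_H3 divides out the
    H3 enrichment so both ratios are invariant to global gain changes.
    """
    ip = np.asarray(ip_signal, dtype=float)
    inp = np.asarray(input_signal, dtype=float)
    if np.any(ip <= 0) or np.any(inp <= 0):
        raise ValueError("signals must be > 0")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    vs_input = ip / (inp / input_fraction)
    if h3_signal is None:
        return (float(vs_input) if vs_input.ndim == 0 else vs_input), None
    h3 = np.asarray(h3_signal, dtype=float)
    if np.any(h3 <= 0):
        raise ValueError("H3 signal must be > 0")
    vs_h3 = vs_input / (h3 / (inp / input_fraction))
    if vs_input.ndim == 0:
        return float(vs_input), float(vs_h3)
    return vs_input, vs_h3


def normalized_lane_profile(lane: TRFLane) -> np.ndarray:
    """Background-subtracted lane profile scaled to a unit peak."""
    x = lane.intensity - float(lane.intensity.min())
    peak = float(x.max())
    if peak <= 0:
        raise ValueError("flat lane profile; nothing to normalize")
    return x / peak
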