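"""Quantitative image-based cytometry: cell-cycle gating and marker summaries.

Per-nucleus DAPI (integrated, proportional to DNA content) and mean EdU
intensities are gated flow-cytometry style: EdU-positive nuclei are S phase;
EdU-negative nuclei split into G1 (2N DAPI mode) and G2/M (4N mode).
Thresholds can be supplied or derived automatically — the EdU cut is the
kernel-density valley between the two largest modes of log-intensity, the
DAPI cut the midpoint between the two DAPI modes of EdU-negative nuclei.
Nuclei with DAPI above twice the 4N mode are treated as doublets and left
unassigned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

__all__ = [
    "CellCyclePhaseGater",
    "gate_phases",
    "edu_positive_fraction",
    "per_phase_summary",
]

PHASES = ("G1", "S", "G2M", "unassigned")
MIN_NUCLEI_FOR_AUTO = 50


def _kde_modes(values: np.ndarray, grid_size: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid, density, and sorted positions of the two largest density modes."""
    kde = gaussian_kde(values)
    lo, hi = float(np.min(values)), float(np.max(values))
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=1e-3 * float(np.max(dens)))
    if peaks.size < 2:
        return grid, dens, grid[peaks]
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    return grid, dens, np.sort(grid[top2])


class CellCyclePhaseGater(BaseEstimator):
    """Assign G1 / S / G2M phases from per-nucleus DAPI and EdU intensities.

    Parameters
    ----------
    edu_threshold
        "auto" (KDE valley on log10 EdU) or an explicit linear-scale value.
    dapi_split
        "auto" (midpoint between the 2N and 4N DAPI modes of EdU-negative
        nuclei) or an explicit value.
    doublet_factor
        Nuclei with DAPI above ``doublet_factor`` times the 4N mode are
        unassigned.

    Fitted attributes: ``edu_threshold_``, ``dapi_split_``, ``dapi_4n_mode_``.
    """

    def __init__(
        self,
        edu_threshold: float | str = "auto",
        dapi_split: float | str = "auto",
        doublet_factor: float = 2.0,
    ):
        self.edu_threshold = edu_threshold
        self.dapi_split = dapi_split
        self.doublet_factor = doublet_factor

    def fit(self, X, y=None):
        """Learn thresholds from a nucleus table with dapi_total and edu_mean."""
        df = self._check_table(X)
        auto = self.edu_threshold == "auto" or self.dapi_split == "auto"
        if auto and len(df) < MIN_NUCLEI_FOR_AUTO:
            raise ValueError(
                f"automatic thresholds need >= {MIN_NUCLEI_FOR_AUTO} nuclei, got {len(df)}"
            )
        edu = df["edu_mean"].to_numpy(dtype=float)
        dapi = df["dapi_total"].to_numpy(dtype=float)

        if self.edu_threshold == "auto":
            log_edu = np.log10(np.maximum(edu, 1e-12))
            grid, dens, modes = _kde_modes(log_edu)
            if modes.size < 2:
                raise ValueError(
                    "EdU log-intensity looks unimodal; pass edu_threshold explicitly"
                )
            between = (grid > modes[0]) & (grid < modes[1])
            valley = grid[between][np.argmin(dens[between])]
            self.edu_threshold_ = float(10**valley)
        else:
            self.edu_threshold_ = float(self.edu_threshold)

        neg = dapi[edu <= self.edu_threshold_]
        if self.dapi_split == "auto":
            if neg.size < 2:
                raise ValueError("no EdU-negative nuclei to derive a DAPI split from")
            _, _, modes = _kde_modes(neg)
            if modes.size < 2:
                warnings.warn(
                    "DAPI distribution of EdU-negative nuclei looks unimodal; "
                    "an explicit dapi_split is required",
                    stacklevel=2,
                )
                raise ValueError(
                    "unimodal DAPI among EdU-negative nuclei; pass dapi_split explicitly"
                )
            self.dapi_split_ = float(modes.mean())
            self.dapi_4n_mode_ = float(modes[1])
        else:
            self.dapi_split_ = float(self.dapi_split)
            above = neg[neg >= self.dapi_split_]
            self.dapi_4n_mode_ = float(np.median(above)) if above.size else float(
                self.dapi_split_ * 4.0 / 3.0
            )
        return self

    def predict(self, X) -> np.ndarray:
        """Phase label per nucleus: S by EdU, then G1/G2M by DAPI, doublets unassigned."""
        df = self._check_table(X)
        edu = df["edu_mean"].to_numpy(dtype=float)
        dapi = df["dapi_total"].to_numpy(dtype=float)
        phase = np.where(edu > self.edu_threshold_, "S", "G1").astype(object)
        negative = edu <= self.edu_threshold_
        phase[negative & (dapi >= self.dapi_split_)] = "G2M"
        phase[dapi > self.doublet_factor * self.dapi_4n_mode_] = "unassigned"
        return phase

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    @staticmethod
    def _check_table(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a per-nucleus DataFrame")
        for col in ("dapi_total", "edu_mean"):
            if col not in X.columns:
                raise ValueError(f"missing column {col!r}")
        if len(X) == 0:
            raise ValueError("empty nucleus table")
        bad = X[["dapi_total", "edu_mean"]].lt(0).any(axis=None)
        if bad:
            raise ValueError("intensities must be >= 0")
        return X


def gate_phases(
    table: pd.DataFrame,
    edu_threshold: float | str = "auto",
    dapi_split: float | str = "auto",
) -> pd.DataFrame:
    """Return a copy of the table with an assigned ``phase`` column."""
    gater = CellCyclePhaseGater(edu_threshold=edu_threshold, dapi_split=dapi_split)
    out = table.copy()
    out["phase"] = gater.fit_predict(table)
    out.attrs["edu_threshold"] = gater.edu_threshold_
    out.attrs["dapi_split"] = gater.dapi_split_
    return out


def edu_positive_fraction(table: pd.DataFrame, edu_threshold: float | str = "auto") -> float:
    """Percent of nuclei with EdU above threshold (S-phase / replicating cells)."""
    if len(table) == 0:
        raise ValueError("empty nucleus table")
    if edu_threshold == "auto":
        gater = CellCyclePhaseGater(dapi_split=1.0).fit(table)
        threshold = gater.edu_threshold_
    else:
        threshold = float(edu_threshold)
    edu = table["edu_mean"].to_numpy(dtype=float)
    return 100.0 * float(np.count_nonzero(edu > threshold)) / len(table)


def per_phase_summary(table: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Mean/SD/count of a marker per assigned phase, plus a pooled row.

    Unassigned nuclei (doublets) are excluded from all summaries.
    """
    if marker not in table.columns:
        raise ValueError(f"marker column {marker!r} not in table")
    if "phase" not in table.columns:
        raise ValueError("phases not assigned; run gate_phases first")
    assigned = table[table["phase"].isin(("G1", "S", "G2M"))]
    rows = []
    for phase in ("G1", "S", "G2M"):
        sub = assigned.loc[assigned["phase"] == phase, marker]
        rows.append(
            {
                "phase": phase,
                "mean": float(sub.mean()) if len(sub) else np.nan,
                "sd": float(sub.std(ddof=1)) if len(sub) > 1 else 0.0 if len(sub) else np.nan,
                "n": int(len(sub)),
            }
        )
    pooled = assigned[marker]
    rows.append(
        {
            "phase": "all",
            "mean": float(pooled.mean()) if len(pooled) else np.nan,
            "sd": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0 if len(pooled) else np.nan,
            "n": int(len(pooled)),
        }
    )
    return pd.DataFrame(rows, columns=["phase", "mean", "sd", "n"])
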