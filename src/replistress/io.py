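"""Plain-text file formats: probe TSV, BED/bedGraph, fiber TSV, assay CSV.

Internal coordinates are 0-based half-open throughout; conversion happens
only at the I/O boundary (``one_based=True`` inputs are shifted on read).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fibers import FiberSet
from .genome import GenomeLayout
from .normalize import RTArray
from .profiles import DifferentialRegion, SmoothedRTProfile

__all__ = [
    "write_probe_table",
    "read_probe_table",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed",
    "read_bed",
    "write_profile_tracks",
    "write_fiber_table",
    "read_fiber_table",
]

PROBE_COLUMNS = ["chrom", "start", "end", "A", "M", "condition", "replicate"]


def write_probe_table(arrays: list[RTArray], path) -> None:
    """Write arrays as one long-format TSV (chrom, start, end, A, M, sample)."""
    frames = []
    for arr in arrays:
        if arr.layout is None:
            raise ValueError("arrays must carry a layout to be written")
        probes = arr.layout.probes
        frames.append(
            pd.DataFrame(
                {
                    "chrom": probes["chrom"],
                    "start": probes["start"],
                    "end": probes["end"],
                    "A": arr.A if arr.A is not None else np.nan,
                    "M": arr.M,
                    "condition": arr.condition,
                    "replicate": arr.replicate,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_table(path, one_based: bool = False) -> tuple[GenomeLayout, list[RTArray]]:
    """Read a probe TSV back into a layout and per-sample arrays.

    Validates sorted, duplicate-free probes with a single spacing, and that
    every sample covers the same grid.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    if one_based:
        df = df.assign(start=df["start"] - 1)

    spacings: set[int] = set()
    chrom_spans: dict[str, int] = {}
    ref_key = None
    arrays = []
    for (condition, replicate), sample in df.groupby(["condition", "replicate"], sort=False):
        for chrom, sub in sample.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            dup = pd.Series(starts).duplicated()
            if dup.any():
                pos = starts[dup.to_numpy()][0]
                raise ValueError(f"duplicate probe at {chrom}:{pos}")
            if np.any(np.diff(starts) <= 0):
                raise ValueError(f"unsorted probe coordinates on {chrom}")
            step = np.unique(np.diff(starts))
            widths = np.unique(ends - starts)
            if step.size > 1 or widths.size > 1:
                raise ValueError(f"mixed probe spacings on {chrom}")
            spacings.update(int(s) for s in step)
            spacings.update(int(w) for w in widths)
            chrom_spans.setdefault(str(chrom), int(ends.max()))
        key = list(zip(sample["chrom"], sample["start"]))
        if ref_key is None:
            ref_key = key
        elif key != ref_key:
            raise ValueError(f"sample {condition}:{replicate} is on a different probe grid")
    if len(spacings) > 1:
        raise ValueError(f"mixed probe spacings across chromosomes: {sorted(spacings)}")
    spacing = int(next(iter(spacings)))
    layout = GenomeLayout(
        chromosomes=tuple(chrom_spans.items()), probe_spacing=spacing
    )

    for (condition, replicate), sub in df.groupby(["condition", "replicate"], sort=False):
        arrays.append(
            RTArray(
                M=sub["M"].to_numpy(dtype=float),
                A=sub["A"].to_numpy(dtype=float),
                layout=layout,
                condition=str(condition),
                replicate=int(replicate),
            )
        )
    return layout, arrays


def write_bedgraph(chrom, start, end, value, path, name: str = "track") -> None:
    """Standards-conformant bedGraph with a track header; NaN rows dropped."""
    value = np.asarray(value, dtype=float)
    keep = np.isfinite(value)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object)[keep],
            "start": np.asarray(start)[keep],
            "end": np.asarray(end)[keep],
            "value": value[keep],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={name}\n")
        df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        skiprows=1,
        names=["chrom", "start", "end", "value"],
    )


def write_profile_tracks(profile: SmoothedRTProfile, prefix) -> list[Path]:
    """Write fit/lower/upper bedGraph tracks for a smoothed profile."""
    prefix = Path(prefix)
    out = []
    for field_name, values in (
        ("fit", profile.fit),
        ("lower", profile.lower),
        ("upper", profile.upper),
    ):
        path = prefix.with_name(prefix.name + f".{field_name}.bedgraph")
        write_bedgraph(
            profile.chrom, profile.start, profile.end, values, path, name=field_name
        )
        out.append(path)
    return out


def write_bed(
    regions: list[DifferentialRegion],
    path,
    layout: GenomeLayout | None = None,
    name: str = "differential_rt",
) -> None:
    """Differential regions as BED: name = direction, score = |mean dRT| x 100."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start))
    for a, b in zip(rows[:-1], rows[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping regions at {a.chrom}:{b.start}")
    if layout is not None:
        for r in rows:
            if r.chrom not in layout.chrom_lengths:
                raise ValueError(f"region on unknown chromosome {r.chrom!r}")
            if r.end > layout.chrom_lengths[r.chrom]:
                raise ValueError(f"region end {r.end} beyond chromosome {r.chrom}")
    with open(path, "w") as fh:
        fh.write(f'track name={name}\n')
        for r in rows:
            score = min(int(round(abs(r.mean_delta) * 100)), 1000)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{score}\n")


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        skiprows=1,
        names=["chrom", "start", "end", "name", "score"],
    )


def write_fiber_table(fiberset: FiberSet, path) -> None:
    fiberset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fiber_table(path) -> FiberSet:
    df = pd.read_csv(path, sep="\t")
    return FiberSet.from_frame(df)
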