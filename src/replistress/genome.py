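"""Genome layouts for array-based replication-timing profiles.

A layout is an ordered set of chromosomes carrying probes on a regular grid,
one probe every ``probe_spacing`` bp (13 kb by default, the density of the
whole-genome tiling arrays this package emulates).  Probe *i* (1-based) on a
chromosome sits at position ``i * spacing`` and represents the half-open
interval ``[ (i-1)*spacing, i*spacing )``; all internal coordinates are
0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

DEFAULT_PROBE_SPACING = 13_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with a regular probe grid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    probe_spacing
        Distance between consecutive probe positions in bp (> 0).
    """

    chromosomes: tuple[tuple[str, int], ...]
    probe_spacing: int = DEFAULT_PROBE_SPACING

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @cached_property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @cached_property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_probes_on(self, chrom: str) -> int:
        return self.chrom_lengths[chrom] // self.probe_spacing

    @cached_property
    def n_probes(self) -> int:
        return sum(self.n_probes_on(name) for name in self.chrom_names)

    @cached_property
    def probes(self) -> pd.DataFrame:
        """Probe table: chrom, start, end, position (one row per probe)."""
        chroms: list[np.ndarray] = []
        starts: list[np.ndarray] = []
        s = self.probe_spacing
        for name, _length in self.chromosomes:
            k = self.n_probes_on(name)
            idx = np.arange(k, dtype=np.int64)
            chroms.append(np.repeat(np.asarray([name], dtype=object), k))
            starts.append(idx * s)
        start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        chrom = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": start,
                "end": start + s,
                "position": start + s,  # probe coordinate used for smoothing
            }
        )

    @cached_property
    def covered_length(self) -> dict[str, int]:
        """Span covered by probes per chromosome (first probe start to last probe end)."""
        return {name: self.n_probes_on(name) * self.probe_spacing for name in self.chrom_names}

    def chrom_slices(self) -> dict[str, slice]:
        """Slice into the concatenated probe vector for each chromosome."""
        out: dict[str, slice] = {}
        offset = 0
        for name in self.chrom_names:
            k = self.n_probes_on(name)
            out[name] = slice(offset, offset + k)
            offset += k
        return out


def make_genome(
    n_chrom: int,
    chrom_length: int,
    spacing: int = DEFAULT_PROBE_SPACING,
) -> GenomeLayout:
    """Build a layout of ``n_chrom`` equal chromosomes named chr1..chrN.

    Each chromosome carries ``floor(chrom_length / spacing)`` probes.  A
    chromosome shorter than one probe spacing yields zero probes and a
    warning (degenerate but permitted).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length <= 0 or spacing <= 0:
        raise ValueError("chrom_length and spacing must be > 0")
    layout = GenomeLayout(
        chromosomes=tuple((f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)),
        probe_spacing=int(spacing),
    )
    if layout.n_probes == 0:
        warnings.warn(
            "layout has no probes (chromosomes shorter than one probe spacing)",
            stacklevel=2,
        )
    return layout
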