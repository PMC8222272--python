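"""End-to-end pipeline: simulate -> normalize -> smooth -> call -> summarize.

One :class:`RunConfig` drives all four analysis tracks (replication timing,
fibers, QIBC, TRF) on synthetic inputs, writing intermediates, a JSON
metrics report and a log.  Identical config + seed gives byte-identical
metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assays import shortening_rate, trf_mean_length
from .cytometry import edu_positive_fraction, gate_phases, per_phase_summary
from .fibers import fiber_summary
from .genome import make_genome
from .io import write_bed, write_fiber_table, write_probe_table, write_profile_tracks
from .normalize import loess_normalize_within, quantile_normalize_between
from .profiles import (
    average_replicates,
    call_differential,
    genome_fraction,
    profile_ci,
    smooth_array,
)
from .synth import (
    FiberSimConfig,
    NucleusSimConfig,
    RTSimConfig,
    TRFSimConfig,
    simulate_arrays,
    simulate_fibers,
    simulate_nuclei,
    simulate_rt_truth,
    simulate_trf_series,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("replistress")


@dataclass
class RTCallParams:
    n_chrom: int = 4
    chrom_length: int = 20_000_000
    probe_spacing: int = 13_000
    bandwidth: float = 3_000_000.0
    level: float = 0.95
    min_probes: int = 8
    span_points: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.span_points <= 1:
            raise ValueError("span_points must be in (0, 1]")
        if self.bandwidth <= self.probe_spacing:
            raise ValueError("bandwidth must exceed probe spacing")


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = ("rt", "fibers", "qibc", "trf")
    rt_sim: RTSimConfig = field(default_factory=RTSimConfig)
    rt_call: RTCallParams = field(default_factory=RTCallParams)
    fibers: FiberSimConfig = field(default_factory=FiberSimConfig)
    nuclei: NucleusSimConfig = field(default_factory=NucleusSimConfig)
    trf: TRFSimConfig = field(default_factory=TRFSimConfig)
    input_paths: dict = field(default_factory=dict)  # optional external inputs

    def __post_init__(self) -> None:
        bad = set(self.stages) - {"rt", "fibers", "qibc", "trf"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_mapping(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "rt_sim": RTSimConfig,
    "rt_call": RTCallParams,
    "fibers": FiberSimConfig,
    "nuclei": NucleusSimConfig,
    "trf": TRFSimConfig,
}


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _from_mapping(_SECTION_TYPES[key], dict(value))
        elif key == "stages":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _seed_for(config: RunConfig, stage: str) -> int:
    offsets = {"rt": 11, "fibers": 23, "qibc": 37, "trf": 53}
    return (int(config.seed) * 101 + offsets[stage]) % (2**31 - 1)


def run_rt_track(config: RunConfig, outdir: Path | None = None) -> dict:
    """Simulate arrays, normalize, smooth, call differential regions."""
    p = config.rt_call
    layout = make_genome(p.n_chrom, p.chrom_length, p.probe_spacing)
    seed = _seed_for(config, "rt")
    truth = simulate_rt_truth(layout, config.rt_sim, seed)
    arrays = simulate_arrays(truth, config.rt_sim, seed)
    if outdir is not None:
        write_probe_table(arrays, outdir / "probes_raw.tsv")

    for arr in arrays:
        arr.M = loess_normalize_within(arr.M, arr.A, span_points=p.span_points)
    normalized = quantile_normalize_between([arr.M for arr in arrays])
    for arr, m in zip(arrays, normalized):
        arr.M = m

    metrics: dict = {}
    band_profiles = {}
    for cond in ("ref", "cond"):
        reps = [a for a in arrays if a.condition == cond]
        smoothed = [smooth_array(a, p.bandwidth, p.level) for a in reps]
        avg_fit = average_replicates(smoothed)
        # CI band fitted to the averaged *normalized* data so the residual
        # variance reflects probe-level noise, not an already-smoothed curve
        avg_raw = np.mean([a.M for a in reps], axis=0)
        band = profile_ci(
            avg_raw, bandwidth=p.bandwidth, level=p.level, layout=layout, condition=cond
        )
        band_profiles[cond] = band
        if outdir is not None:
            write_profile_tracks(band, outdir / f"profile_{cond}")
        metrics[f"rt_mean_fit_{cond}"] = float(np.nanmean(avg_fit))

    regions = call_differential(band_profiles["cond"], band_profiles["ref"], p.min_probes)
    fractions = genome_fraction(regions, layout, per_chromosome=False)
    if outdir is not None:
        write_bed(regions, outdir / "differential_regions.bed", layout)
    for _, row in fractions.iterrows():
        metrics[f"rt_percent_{row['direction']}"] = round(float(row["percent"]), 6)
    metrics["rt_n_regions"] = len(regions)
    metrics["rt_true_percent_earlier"] = round(100.0 * truth.shifted_fraction("earlier"), 6)
    metrics["rt_true_percent_later"] = round(100.0 * truth.shifted_fraction("later"), 6)
    return metrics


def run_fiber_track(config: RunConfig, outdir: Path | None = None) -> dict:
    fiberset = simulate_fibers(config.fibers, _seed_for(config, "fibers"))
    if outdir is not None:
        write_fiber_table(fiberset, outdir / "fibers.tsv")
    summary = fiber_summary(fiberset)
    if outdir is not None:
        summary.to_csv(outdir / "fiber_stats.csv", index=False)
    return {
        f"fiber_{row['statistic']}": round(float(row["value"]), 6)
        for _, row in summary.iterrows()
        if np.isfinite(row["value"])
    }


def run_qibc_track(config: RunConfig, outdir: Path | None = None) -> dict:
    table = simulate_nuclei(config.nuclei, _seed_for(config, "qibc"))
    gated = gate_phases(table)
    if outdir is not None:
        gated.to_csv(outdir / "nuclei_gated.csv", index=False)
    metrics = {
        "qibc_edu_positive_percent": round(
            edu_positive_fraction(table, gated.attrs["edu_threshold"]), 6
        ),
        "qibc_phase_accuracy_percent": round(
            100.0
            * float(np.mean(gated["phase"].to_numpy() == gated["true_phase"].to_numpy())),
            6,
        ),
    }
    for marker in ("gh2ax_mean", "n53bp1_foci"):
        summary = per_phase_summary(gated, marker)
        if outdir is not None:
            summary.to_csv(outdir / f"qibc_{marker}_summary.csv", index=False)
        for _, row in summary.iterrows():
            if row["n"]:
                metrics[f"qibc_{marker}_{row['phase']}_mean"] = round(float(row["mean"]), 6)
    return metrics


def run_trf_track(config: RunConfig, outdir: Path | None = None) -> dict:
    series = simulate_trf_series(config.trf, _seed_for(config, "trf"))
    lengths = [trf_mean_length(lane, series.ladder) for lane in series.lanes]
    pds = [lane.pd_at_sampling for lane in series.lanes]
    if outdir is not None:
        import pandas as pd

        pd.DataFrame({"pd": pds, "mean_length_kb": lengths}).to_csv(
            outdir / "trf_mean_lengths.csv", index=False
        )
    metrics = {
        "trf_initial_mean_kb": round(lengths[0], 6),
        "trf_final_mean_kb": round(lengths[-1], 6),
    }
    if len(set(pds)) > 1:
        metrics["trf_shortening_rate_bp_per_pd"] = round(
            shortening_rate(lengths, pds), 6
        )
    return metrics


_TRACKS = {
    "rt": run_rt_track,
    "fibers": run_fiber_track,
    "qibc": run_qibc_track,
    "trf": run_trf_track,
}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all configured tracks, writing intermediates and a metrics report."""
    for name, path in config.input_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input path {name!r} does not exist: {path}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("replistress %s seed=%s stages=%s", __version__, config.seed, config.stages)
        metrics: dict = {"seed": int(config.seed), "version": __version__}
        for stage in config.stages:
            log.info("stage %s", stage)
            try:
                metrics.update(_TRACKS[stage](config, outdir))
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("done")
        return metrics
    finally:
        log.removeHandler(handler)
        handler.close()
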