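"""Synthetic data generators for every assay the pipeline quantifies.

Each generator is a pure function of its configuration and an integer seed,
producing data with the statistical structure the downstream analyses
assume:

* RT truth: piecewise-constant replication-timing domains (log2 units,
  positive = early) with a second condition carrying injected earlier/later
  shifts over an annotated fraction of the genome;
* two-channel arrays: the truth corrupted by replicate Gaussian noise and an
  intensity-dependent (MA) dye-bias curve;
* SMARD fibers from the 4-cycle EdU/IdU/chase labeling scheme, with per-fork
  speeds, stall events, in-pulse origin firing and optional terminal
  telomere-FISH tracts;
* QIBC nucleus tables as 2N/4N DAPI mixtures with EdU-positive S phase and
  phase-dependent damage markers;
* TRF lanes: smear intensity profiles of lognormal telomere-length
  distributions shortening linearly with population doublings, mapped
  through a monotone gel-ladder calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import LadderCalibration, TRFLane
from .fibers import Fiber, FiberSet
from .genome import GenomeLayout

__all__ = [
    "RTSimConfig",
    "FiberSimConfig",
    "NucleusSimConfig",
    "TRFSimConfig",
    "SimConfig",
    "RTTruth",
    "TRFSeries",
    "simulate_rt_truth",
    "simulate_arrays",
    "simulate_fibers",
    "simulate_nuclei",
    "simulate_trf_series",
]

# fixed spawn keys so each generator has an independent, reproducible stream
_STREAMS = {"rt_truth": 0, "arrays": 1, "fibers": 2, "nuclei": 3, "trf": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],))
    )


def _lognormal_mean_sd(rng, mean: float, sd: float, size=None):
    """Lognormal draws parametrized by arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


@dataclass
class RTSimConfig:
    """Replication-timing truth and array noise model.

    Domains are exponential in length (mean 1 Mb, truncated to 100 kb-5 Mb)
    with values alternating in sign around +-1 log2 unit.  Shifts are
    injected into the second condition as contiguous runs of domains grown
    to ``shift_interval_target_bp`` (multi-Mb differential regions), until
    the configured genome fraction is covered to within one domain.
    """

    noise_sd: float = 0.3
    dye_bias: tuple[float, ...] = (0.0, 0.15, 0.08)  # poly coefs in (A - a_mean)
    n_replicates: int = 2
    a_mean: float = 10.0
    a_sd: float = 1.0
    domain_mean_bp: float = 1_000_000.0
    domain_min_bp: float = 100_000.0
    domain_max_bp: float = 5_000_000.0
    domain_value_mean: float = 1.0
    domain_value_sd: float = 0.2
    shift_frac_earlier: float = 0.03
    shift_frac_later: float = 0.0
    shift_delta: float = 1.5
    shift_interval_target_bp: float = 3_000_000.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.a_sd < 0 or self.domain_value_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for frac in (self.shift_frac_earlier, self.shift_frac_later):
            if not 0 <= frac <= 1:
                raise ValueError("shift fractions must lie in [0, 1]")
        if not 0 < self.domain_min_bp <= self.domain_max_bp:
            raise ValueError("bad domain length bounds")
        if self.shift_delta <= 0:
            raise ValueError("shift_delta must be > 0")


@dataclass
class FiberSimConfig:
    """SMARD fiber generator under the EdU(20')/IdU(20')/chase labeling cycle.

    Forks caught in transit carry an EdU tract followed by an IdU tract
    (speed x pulse); with probability ``stall_prob`` a fork arrests at a
    uniform time within the first pulse and leaves an isolated EdU tract.
    Origins firing during the first pulse leave an EdU tract flanked by two
    diverging IdU tracts.  Segments below the optical resolution floor
    (``min_segment_kb``) are dropped.
    """

    n_fibers: int = 500
    fiber_length_kb: float = 1000.0
    fork_speed_mean: float = 2.0  # kb/min
    fork_speed_sd: float = 0.3
    stall_prob: float = 0.2
    fork_density_per_mb: float = 0.5  # in-transit forks
    origin_density_per_mb: float = 0.3  # origins firing during pulse 1
    pulse1_min: float = 20.0
    pulse2_min: float = 20.0
    telomere_fraction: float = 0.0
    telomere_mean_kb: float = 9.0
    telomere_sd_kb: float = 1.2
    telomere_replicating_prob: float = 0.5
    telomere_fork_speed_mean: float = 1.0
    telomere_fork_speed_sd: float = 0.15
    min_segment_kb: float = 1.0

    def __post_init__(self) -> None:
        if self.fork_speed_mean <= 0 or self.telomere_fork_speed_mean <= 0:
            raise ValueError("fork speeds must be > 0")
        for frac in (self.stall_prob, self.telomere_fraction, self.telomere_replicating_prob):
            if not 0 <= frac <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fork_speed_sd < 0 or self.telomere_fork_speed_sd < 0:
            raise ValueError("speed SDs must be >= 0")
        if self.fiber_length_kb <= 0 or self.n_fibers < 1:
            raise ValueError("need positive fiber length and count")


@dataclass
class NucleusSimConfig:
    """2N/4N DAPI mixture with EdU-positive S phase and phase-wise markers."""

    n_nuclei: int = 5000
    phase_proportions: tuple[float, float, float] = (0.62, 0.18, 0.20)  # G1, S, G2M
    dapi_g1_mean: float = 100.0
    dapi_cv: float = 0.05
    edu_negative_mean: float = 1.0
    edu_separation: float = 10.0
    edu_log_sd: float = 0.25
    gh2ax_means: dict = field(default_factory=lambda: {"G1": 1.0, "S": 2.0, "G2M": 1.2})
    gh2ax_cv: float = 0.3
    foci_means: dict = field(default_factory=lambda: {"G1": 2.0, "S": 4.0, "G2M": 3.0})

    def __post_init__(self) -> None:
        props = np.asarray(self.phase_proportions, dtype=float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("phase proportions must be >= 0 and sum to 1")
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if self.dapi_cv < 0 or self.edu_log_sd < 0 or self.gh2ax_cv < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass
class TRFSimConfig:
    """TRF smear series: lognormal telomere lengths shortening with PD."""

    initial_mean_kb: float = 9.0
    shortening_rate_bp_per_pd: float = 150.0
    pds: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0)
    length_cv: float = 0.35
    ladder_kb: tuple[float, ...] = (2, 3, 4, 6, 8, 12, 16, 24, 32)
    gel_intercept_mm: float = 95.0  # distance = intercept - slope * ln(kb)
    gel_slope_mm: float = 22.0
    grid_size: int = 200
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.shortening_rate_bp_per_pd < 0:
            raise ValueError("shortening rate must be >= 0")
        final = self.initial_mean_kb - self.shortening_rate_bp_per_pd * max(self.pds) / 1000.0
        if final <= 0:
            raise ValueError("mean telomere length reaches <= 0 within the PD range")
        if self.length_cv <= 0 or self.noise_cv < 0:
            raise ValueError("bad dispersion parameters")


@dataclass
class SimConfig:
    """Top-level simulation configuration: one seed, one block per assay."""

    seed: int = 0
    rt: RTSimConfig = field(default_factory=RTSimConfig)
    fibers: FiberSimConfig = field(default_factory=FiberSimConfig)
    nuclei: NucleusSimConfig = field(default_factory=NucleusSimConfig)
    trf: TRFSimConfig = field(default_factory=TRFSimConfig)


@dataclass
class RTTruth:
    """Latent per-probe RT values for a reference and a shifted condition."""

    layout: GenomeLayout
    reference: np.ndarray
    condition: np.ndarray
    domains: pd.DataFrame  # chrom, start, end, value
    shifts: pd.DataFrame  # chrom, start, end, direction, delta

    def __post_init__(self) -> None:
        for _, row in self.shifts.iterrows():
            if (row["direction"] == "earlier") != (row["delta"] > 0):
                raise ValueError("shift direction inconsistent with delta sign")
            if row["end"] > self.layout.chrom_lengths[row["chrom"]]:
                raise ValueError("shift interval outside chromosome")

    def shifted_fraction(self, direction: str) -> float:
        total = sum(length for _, length in self.layout.chromosomes)
        sub = self.shifts[self.shifts["direction"] == direction]
        return float((sub["end"] - sub["start"]).sum() / total)


def _draw_domains(rng, length: int, cfg: RTSimConfig) -> np.ndarray:
    """Domain boundaries (end coordinates) covering [0, length)."""
    ends = []
    pos = 0
    while pos < length:
        while True:
            d = rng.exponential(cfg.domain_mean_bp)
            if cfg.domain_min_bp <= d <= cfg.domain_max_bp:
                break
        pos = min(pos + d, length)
        ends.append(int(round(pos)))
    ends[-1] = length
    return np.asarray(ends, dtype=np.int64)


def simulate_rt_truth(layout: GenomeLayout, config: RTSimConfig, seed: int) -> RTTruth:
    """Piecewise-constant RT truth with annotated shifts in a second condition."""
    if config.shift_frac_earlier + config.shift_frac_later > 0.5:
        raise ValueError("total shift fraction > 0.5 is unidentifiable")
    rng = _rng(seed, "rt_truth")

    dom_rows = []
    for chrom, length in layout.chromosomes:
        ends = _draw_domains(rng, length, config)
        starts = np.concatenate([[0], ends[:-1]])
        sign = rng.choice([-1.0, 1.0])
        for s, e in zip(starts, ends):
            value = sign * abs(rng.normal(config.domain_value_mean, config.domain_value_sd))
            dom_rows.append({"chrom": chrom, "start": int(s), "end": int(e), "value": value})
            sign = -sign
    domains = pd.DataFrame(dom_rows)

    probes = layout.probes
    mid = probes["start"].to_numpy() + layout.probe_spacing / 2.0
    reference = np.empty(layout.n_probes)
    probe_domain = np.empty(layout.n_probes, dtype=np.int64)
    for chrom, sl in layout.chrom_slices().items():
        sub = domains[domains["chrom"] == chrom]
        idx = np.searchsorted(sub["end"].to_numpy(), mid[sl.start : sl.stop], side="right")
        idx = np.minimum(idx, len(sub) - 1)
        reference[sl] = sub["value"].to_numpy()[idx]
        probe_domain[sl] = sub.index.to_numpy()[idx]

    condition = reference.copy()
    shifted = np.zeros(len(domains), dtype=bool)
    dom_len = (domains["end"] - domains["start"]).to_numpy()
    dom_chrom = domains["chrom"].to_numpy()
    genome = sum(length for _, length in layout.chromosomes)

    shift_rows = []
    for direction, frac in (
        ("earlier", config.shift_frac_earlier),
        ("later", config.shift_frac_later),
    ):
        if frac <= 0:
            continue
        delta = config.shift_delta if direction == "earlier" else -config.shift_delta
        target = frac * genome
        realized = 0.0
        for _attempt in range(10_000):
            if realized >= target:
                break
            free = np.flatnonzero(~shifted)
            if free.size == 0:
                break
            i = int(rng.choice(free))
            remaining = target - realized
            if dom_len[i] - remaining > remaining:
                break  # any new interval overshoots worse than stopping here
            run = [i]
            run_len = float(dom_len[i])
            # grow the run over free same-chromosome neighbours up to the
            # target interval scale (or the remaining genome-wide target),
            # adding a domain only while it brings the run closer to the cap
            cap = min(config.shift_interval_target_bp, remaining)
            left, right = i - 1, i + 1
            while run_len < cap:
                can_r = (
                    right < len(domains)
                    and not shifted[right]
                    and dom_chrom[right] == dom_chrom[i]
                )
                can_l = left >= 0 and not shifted[left] and dom_chrom[left] == dom_chrom[i]
                if can_r:
                    extra = dom_len[right]
                elif can_l:
                    extra = dom_len[left]
                else:
                    break
                if run_len + extra > cap and (run_len + extra - cap) > (cap - run_len):
                    break
                if can_r:
                    run.append(right)
                    right += 1
                else:
                    run.insert(0, left)
                    left -= 1
                run_len += extra
            shifted[run] = True
            in_run = np.isin(probe_domain, run)
            condition[in_run] += delta
            realized += run_len
            shift_rows.append(
                {
                    "chrom": dom_chrom[i],
                    "start": int(domains["start"].iloc[run[0]]),
                    "end": int(domains["end"].iloc[run[-1]]),
                    "direction": direction,
                    "delta": delta,
                }
            )
    shifts = pd.DataFrame(
        shift_rows, columns=["chrom", "start", "end", "direction", "delta"]
    )
    return RTTruth(
        layout=layout,
        reference=reference,
        condition=condition,
        domains=domains,
        shifts=shifts,
    )


def _dye_bias(coefs: tuple[float, ...], a_centered: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a_centered)
    for power, c in enumerate(coefs):
        out = out + c * a_centered**power
    return out


def simulate_arrays(truth: RTTruth, config: RTSimConfig, seed: int):
    """Noisy two-channel arrays for both conditions, ``n_replicates`` each.

    Per probe the ideal log-ratio M equals the truth; the observed M adds
    Gaussian replicate noise and a dye-bias polynomial in A (mean log2
    intensity, drawn Normal(a_mean, a_sd)).
    """
    from .normalize import RTArray  # local import to avoid cycle

    rng = _rng(seed, "arrays")
    n = truth.layout.n_probes
    arrays = []
    for cond_name, values in (("ref", truth.reference), ("cond", truth.condition)):
        for rep in range(1, config.n_replicates + 1):
            A = rng.normal(config.a_mean, config.a_sd, n)
            bias = _dye_bias(config.dye_bias, A - config.a_mean)
            noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
            M = values + bias + noise
            arrays.append(
                RTArray(M=M, A=A, layout=truth.layout, condition=cond_name, replicate=rep)
            )
    return arrays


# ---------------------------------------------------------------------------
# fibers


def _truncated_speed(rng, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    return float(np.maximum(rng.normal(mean, sd), 0.05 * mean))


def _paint_segments(
    region: tuple[float, float],
    edu: list[tuple[float, float]],
    idu: list[tuple[float, float]],
) -> list[tuple[str, float]]:
    """Label the region from interval lists; EdU wins overlaps (first pulse)."""
    lo, hi = region
    clip = lambda iv: (max(iv[0], lo), min(iv[1], hi))
    edu = [clip(iv) for iv in edu]
    idu = [clip(iv) for iv in idu]
    edges = {lo, hi}
    for a, b in edu + idu:
        if b > a:
            edges.update((a, b))
    pts = sorted(edges)
    segments = []
    for a, b in zip(pts[:-1], pts[1:]):
        if b <= a:
            continue
        m = (a + b) / 2.0
        if any(s < m < e for s, e in edu):
            label = "EDU"
        elif any(s < m < e for s, e in idu):
            label = "IDU"
        else:
            label = "U"
        segments.append((label, b - a))
    return segments


def _rle_clean(segments: list[tuple[str, float]], min_kb: float) -> list[tuple[str, float]]:
    """Merge equal neighbours, drop sub-resolution segments, merge again."""

    def merge(segs):
        out: list[list] = []
        for label, kb in segs:
            if out and out[-1][0] == label:
                out[-1][1] += kb
            else:
                out.append([label, kb])
        return [(l, k) for l, k in out]

    segs = merge(segments)
    segs = [(l, k) for l, k in segs if k >= min_kb or l == "TEL"]
    return merge(segs)


def simulate_fibers(config: FiberSimConfig, seed: int) -> FiberSet:
    """Fiber set under the two-pulse labeling scheme; see :class:`FiberSimConfig`."""
    rng = _rng(seed, "fibers")
    p1, p2 = config.pulse1_min, config.pulse2_min
    fibers = []
    origin_truth: dict[str, list[float]] = {}
    for i in range(config.n_fibers):
        L = config.fiber_length_kb
        edu: list[tuple[float, float]] = []
        idu: list[tuple[float, float]] = []
        tel_len = 0.0
        ev_start = 0.0
        if config.telomere_fraction > 0 and rng.random() < config.telomere_fraction:
            tel_len = float(
                _lognormal_mean_sd(rng, config.telomere_mean_kb, config.telomere_sd_kb)
            )
            tel_len = min(tel_len, 0.4 * L)
            ev_start = tel_len
            if rng.random() < config.telomere_replicating_prob:
                v = _truncated_speed(
                    rng, config.telomere_fork_speed_mean, config.telomere_fork_speed_sd
                )
                # fork that traversed the telomere: IdU in continuity with FISH
                idu.append((tel_len, tel_len + v * p2))
                edu.append((tel_len + v * p2, tel_len + v * (p1 + p2)))
                ev_start = tel_len + v * (p1 + p2) + 5.0
            else:
                ev_start = tel_len + rng.uniform(10.0, 30.0)
        region = max(L - ev_start, 0.0)

        # events are placed wholly inside the fiber: partial tracks running
        # off a fiber end would not be scored and are not emulated
        n_forks = rng.poisson(config.fork_density_per_mb * region / 1000.0)
        for _ in range(n_forks):
            direction = 1.0 if rng.random() < 0.5 else -1.0
            v = _truncated_speed(rng, config.fork_speed_mean, config.fork_speed_sd)
            stalled = rng.random() < config.stall_prob
            extent = v * (rng.uniform(0.0, p1) if stalled else p1 + p2)
            if extent > L - ev_start or extent <= 0:
                continue
            x0 = rng.uniform(ev_start, L - extent)  # left edge of the event
            x = x0 if direction > 0 else x0 + extent  # fork start position
            if stalled:
                edu.append((x0, x0 + extent))
            else:
                e_iv = sorted((x, x + direction * v * p1))
                i_iv = sorted((x + direction * v * p1, x + direction * v * (p1 + p2)))
                edu.append(tuple(e_iv))
                idu.append(tuple(i_iv))

        fiber_origins: list[float] = []
        n_origins = rng.poisson(config.origin_density_per_mb * region / 1000.0)
        for _ in range(n_origins):
            t0 = rng.uniform(0.0, p1)
            vl = _truncated_speed(rng, config.fork_speed_mean, config.fork_speed_sd)
            vr = _truncated_speed(rng, config.fork_speed_mean, config.fork_speed_sd)
            left_ext = vl * (p1 - t0 + p2)
            right_ext = vr * (p1 - t0 + p2)
            if left_ext + right_ext > L - ev_start:
                continue
            x = rng.uniform(ev_start + left_ext, L - right_ext)
            el, er = x - vl * (p1 - t0), x + vr * (p1 - t0)
            edu.append((el, er))
            idu.append((el - vl * p2, el))
            idu.append((er, er + vr * p2))
            fiber_origins.append(x)

        painted = _paint_segments((tel_len, L), edu, idu)
        segments = ([("TEL", tel_len)] if tel_len > 0 else []) + painted
        segments = _rle_clean(segments, config.min_segment_kb)
        if segments:
            fid = f"fiber{i + 1:05d}"
            fibers.append(Fiber(fid, tuple(segments)))
            if fiber_origins:
                origin_truth[fid] = sorted(fiber_origins)
    return FiberSet(fibers, truth=origin_truth)


# ---------------------------------------------------------------------------
# nuclei


def simulate_nuclei(config: NucleusSimConfig, seed: int) -> pd.DataFrame:
    """Per-nucleus table with true phases, DAPI/EdU intensities and markers."""
    rng = _rng(seed, "nuclei")
    n = config.n_nuclei
    phases = rng.choice(["G1", "S", "G2M"], size=n, p=list(config.phase_proportions))
    dapi = np.empty(n)
    edu = np.empty(n)
    gh2ax = np.empty(n)
    foci = np.zeros(n, dtype=np.int64)
    g1 = config.dapi_g1_mean
    scatter = np.exp(rng.normal(0.0, config.dapi_cv, n))
    dapi[phases == "G1"] = g1 * scatter[phases == "G1"]
    dapi[phases == "G2M"] = 2.0 * g1 * scatter[phases == "G2M"]
    n_s = int(np.count_nonzero(phases == "S"))
    dapi[phases == "S"] = g1 * rng.uniform(1.0, 2.0, n_s) * scatter[phases == "S"]

    log_sd = config.edu_log_sd
    neg_mu = np.log(config.edu_negative_mean) - log_sd**2 / 2.0
    pos_mu = np.log(config.edu_negative_mean * config.edu_separation) - log_sd**2 / 2.0
    edu = rng.lognormal(neg_mu, log_sd, n)
    edu[phases == "S"] = rng.lognormal(pos_mu, log_sd, n_s)

    g_sigma = np.sqrt(np.log1p(config.gh2ax_cv**2))
    for phase in ("G1", "S", "G2M"):
        mask = phases == phase
        k = int(mask.sum())
        mu = np.log(config.gh2ax_means[phase]) - g_sigma**2 / 2.0
        gh2ax[mask] = rng.lognormal(mu, g_sigma, k)
        foci[mask] = rng.poisson(config.foci_means[phase], k)

    return pd.DataFrame(
        {
            "nucleus_id": [f"n{i + 1:06d}" for i in range(n)],
            "true_phase": phases,
            "dapi_total": dapi,
            "edu_mean": edu,
            "gh2ax_mean": gh2ax,
            "n53bp1_foci": foci,
        }
    )


# ---------------------------------------------------------------------------
# TRF lanes


@dataclass
class TRFSeries:
    lanes: list[TRFLane]
    ladder: LadderCalibration


def simulate_trf_series(config: TRFSimConfig, seed: int) -> TRFSeries:
    """TRF smear lanes for each sampled PD, plus the ladder calibration.

    Lane intensity at a gel position is the lognormal length density times
    fragment length (longer fragments bind proportionally more probe) times
    the local kb-per-mm Jacobian, with optional multiplicative bin noise.
    """
    rng = _rng(seed, "trf")
    kb = np.asarray(config.ladder_kb, dtype=float)
    distances = config.gel_intercept_mm - config.gel_slope_mm * np.log(kb)
    ladder = LadderCalibration(distances, kb)

    grid = np.linspace(distances.min(), distances.max(), config.grid_size)
    lengths = ladder(grid)
    jac = np.abs(np.gradient(lengths, grid))

    lanes = []
    for pd_val in config.pds:
        mean = config.initial_mean_kb - config.shortening_rate_bp_per_pd * pd_val / 1000.0
        sd = config.length_cv * mean
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        sigma = np.sqrt(sigma2)
        dens = np.exp(-((np.log(lengths) - mu) ** 2) / (2 * sigma2)) / (
            lengths * sigma * np.sqrt(2 * np.pi)
        )
        od = dens * lengths * jac
        if config.noise_cv > 0:
            od = od * np.exp(rng.normal(0.0, config.noise_cv, od.size))
        lanes.append(
            TRFLane(distance=grid, intensity=od, pd_at_sampling=float(pd_val))
        )
    return TRFSeries(lanes=lanes, ladder=ladder)
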