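import numpy as np
import pandas as pd
import pytest

from replistress import make_genome, quantile_normalize_between, smooth_array
from replistress.fibers import _count_forks
from replistress.synth import (
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
from replistress import (
    detect_origins,
    inter_origin_distances,
    track_lengths,
    trf_mean_length,
)


class TestRTTruth:
    def test_zero_shift_conditions_identical(self, small_layout):
        cfg = RTSimConfig(shift_frac_earlier=0.0, shift_frac_later=0.0)
        truth = simulate_rt_truth(small_layout, cfg, seed=1)
        assert np.array_equal(truth.reference, truth.condition)
        assert len(truth.shifts) == 0

    def test_shift_fraction_realized_within_one_domain(self):
        layout = make_genome(10, 20_000_000, 13_000)
        cfg = RTSimConfig(shift_frac_earlier=0.03)
        genome = sum(l for _, l in layout.chromosomes)
        for seed in (1, 2, 3):
            truth = simulate_rt_truth(layout, cfg, seed=seed)
            realized = truth.shifted_fraction("earlier")
            assert abs(realized - 0.03) <= cfg.domain_max_bp / genome
            # annotations agree with the probe-level difference
            shifted_probes = np.mean(truth.condition - truth.reference > 1.0)
            assert shifted_probes == pytest.approx(realized, abs=0.002)

    def test_direction_sign_convention(self, small_layout):
        cfg = RTSimConfig(shift_frac_earlier=0.05, shift_frac_later=0.05)
        truth = simulate_rt_truth(small_layout, cfg, seed=2)
        for _, row in truth.shifts.iterrows():
            assert (row.direction == "earlier") == (row.delta > 0)

    def test_excessive_shift_rejected(self, small_layout):
        cfg = RTSimConfig(shift_frac_earlier=0.3, shift_frac_later=0.3)
        with pytest.raises(ValueError, match="0.5"):
            simulate_rt_truth(small_layout, cfg, seed=1)

    def test_deterministic(self, small_layout):
        cfg = RTSimConfig()
        a = simulate_rt_truth(small_layout, cfg, seed=9)
        b = simulate_rt_truth(small_layout, cfg, seed=9)
        assert np.array_equal(a.reference, b.reference)
        assert np.array_equal(a.condition, b.condition)
        pd.testing.assert_frame_equal(a.domains, b.domains)

    def test_domain_lengths_respect_bounds(self, small_layout):
        cfg = RTSimConfig()
        truth = simulate_rt_truth(small_layout, cfg, seed=4)
        lengths = truth.domains["end"] - truth.domains["start"]
        # all but the chromosome-trimmed last domains obey the minimum
        interior = truth.domains.groupby("chrom").apply(
            lambda g: lengths.loc[g.index[:-1]], include_groups=False
        )
        assert (interior <= cfg.domain_max_bp).all()


class TestArrays:
    def test_zero_noise_zero_bias_exact(self, clean_truth):
        truth, _ = clean_truth
        cfg = RTSimConfig(noise_sd=0.0, dye_bias=(0.0,))
        arrays = simulate_arrays(truth, cfg, seed=1)
        for arr in arrays:
            target = truth.reference if arr.condition == "ref" else truth.condition
            assert np.allclose(arr.M, target)

    def test_constant_bias_shifts_m(self, clean_truth):
        truth, _ = clean_truth
        cfg = RTSimConfig(noise_sd=0.0, dye_bias=(0.25,))
        arrays = simulate_arrays(truth, cfg, seed=1)
        assert np.allclose(arrays[0].M, truth.reference + 0.25)

    def test_noise_moment(self):
        layout = make_genome(1, 130_000_000, 13_000)  # 10000 probes
        cfg = RTSimConfig(noise_sd=0.3, dye_bias=(0.0, 0.15, 0.08), n_replicates=1)
        truth = simulate_rt_truth(layout, RTSimConfig(shift_frac_earlier=0.0), seed=5)
        arr = simulate_arrays(truth, cfg, seed=5)[0]
        x = arr.A - cfg.a_mean
        bias = 0.15 * x + 0.08 * x**2
        resid = arr.M - truth.reference - bias
        n = resid.size
        se = 0.3 / np.sqrt(2 * n)
        assert abs(np.std(resid) - 0.3) < 3 * se

    def test_deterministic(self, clean_truth):
        truth, cfg = clean_truth
        a = simulate_arrays(truth, cfg, seed=3)
        b = simulate_arrays(truth, cfg, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.M, y.M) and np.array_equal(x.A, y.A)

    def test_zero_noise_inverts_through_normalization_and_smoothing(self):
        """Noise-free arrays recover the truth exactly at probes further than
        the smoothing bandwidth from any domain boundary."""
        layout = make_genome(2, 20_000_000, 13_000)
        cfg = RTSimConfig(
            noise_sd=0.0,
            dye_bias=(0.0,),
            domain_mean_bp=9e6,
            domain_min_bp=8e6,
            domain_max_bp=10e6,
            shift_frac_earlier=0.0,
        )
        truth = simulate_rt_truth(layout, cfg, seed=6)
        arrays = simulate_arrays(truth, cfg, seed=6)
        norm = quantile_normalize_between([a.M for a in arrays])
        for arr, m in zip(arrays, norm):
            arr.M = m
        prof = smooth_array(arrays[0], bandwidth=3e6)
        probes = layout.probes
        bounds = truth.domains
        far = np.ones(layout.n_probes, dtype=bool)
        for i, row in probes.iterrows():
            edges = bounds[bounds.chrom == row.chrom]["end"].to_numpy()[:-1]
            starts = bounds[bounds.chrom == row.chrom]["start"].to_numpy()[1:]
            cuts = np.union1d(edges, starts)
            if cuts.size and np.min(np.abs(cuts - row.position)) <= 3e6:
                far[i] = False
            if row.position <= 3e6 or row.position >= layout.chrom_lengths[row.chrom] - 3e6:
                far[i] = False
        assert far.sum() > 50
        assert np.nanmax(np.abs(prof.fit[far] - truth.reference[far])) < 1e-6


class TestFiberSim:
    def test_no_stalls_no_isolated_edu(self):
        cfg = FiberSimConfig(n_fibers=300, stall_prob=0.0, origin_density_per_mb=0.0)
        fs = simulate_fibers(cfg, seed=1)
        stalled, progressing = _count_forks(fs)
        assert stalled == 0 and progressing > 0

    def test_fixed_speed_tracks_are_40kb(self):
        cfg = FiberSimConfig(
            n_fibers=2000,
            fork_speed_sd=0.0,
            stall_prob=0.0,
            fork_density_per_mb=0.02,
            origin_density_per_mb=0.0,
        )
        fs = simulate_fibers(cfg, seed=1)
        tracks = [t for f in fs for t in track_lengths(f)]
        assert len(tracks) > 10
        assert np.allclose(tracks, 40.0)

    def test_no_telomere_fraction_no_tel_segments(self):
        cfg = FiberSimConfig(n_fibers=200, telomere_fraction=0.0)
        fs = simulate_fibers(cfg, seed=2)
        assert all("TEL" not in f.labels for f in fs)

    def test_detected_origin_centers_match_truth(self):
        cfg = FiberSimConfig(
            n_fibers=200,
            fiber_length_kb=2000,
            fork_density_per_mb=0.0,
            origin_density_per_mb=1.0,
            fork_speed_sd=0.0,
            stall_prob=0.0,
        )
        fs = simulate_fibers(cfg, seed=3)
        n_checked = 0
        for fiber in fs:
            truth = np.asarray(fs.truth.get(fiber.fiber_id, []))
            if truth.size == 0:
                continue
            # precondition: diverging forks of neighbouring origins must not
            # have merged (EdU extends up to 40 kb either side of an origin)
            if truth.size > 1 and np.min(np.diff(truth)) < 160.0:
                continue
            for center in detect_origins(fiber):
                n_checked += 1
                assert np.min(np.abs(truth - center)) < 1.0
        assert n_checked > 50

    def test_iod_matches_poisson_spacing(self):
        """Mean IOD ~ 1000/density per Mb (long fibers, right-censoring small)."""
        cfg = FiberSimConfig(
            n_fibers=150,
            fiber_length_kb=20_000,
            fork_density_per_mb=0.0,
            origin_density_per_mb=1.0,
            stall_prob=0.0,
        )
        fs = simulate_fibers(cfg, seed=4)
        iods = inter_origin_distances(fs)
        assert len(iods) > 500
        assert np.mean(iods) == pytest.approx(1000.0, rel=0.10)

    def test_deterministic(self):
        cfg = FiberSimConfig(n_fibers=50, telomere_fraction=0.3)
        a = simulate_fibers(cfg, seed=5).to_frame()
        b = simulate_fibers(cfg, seed=5).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            FiberSimConfig(fork_speed_mean=0.0)


class TestNucleusSim:
    def test_pure_g1_population(self):
        cfg = NucleusSimConfig(n_nuclei=500, phase_proportions=(1.0, 0.0, 0.0))
        table = simulate_nuclei(cfg, seed=1)
        assert (table["true_phase"] == "G1").all()
        assert table["edu_mean"].max() < 5.0  # EdU-negative background only

    def test_g2m_dapi_twice_g1(self):
        table = simulate_nuclei(NucleusSimConfig(n_nuclei=10_000), seed=2)
        means = table.groupby("true_phase")["dapi_total"].mean()
        assert means["G2M"] / means["G1"] == pytest.approx(2.0, rel=0.05)

    def test_byte_identical_under_seed(self):
        cfg = NucleusSimConfig(n_nuclei=300)
        a = simulate_nuclei(cfg, seed=3).to_csv()
        b = simulate_nuclei(cfg, seed=3).to_csv()
        assert a == b

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            NucleusSimConfig(phase_proportions=(0.5, 0.2, 0.2))


class TestTRFSim:
    def test_zero_rate_zero_noise_identical_lanes(self):
        cfg = TRFSimConfig(shortening_rate_bp_per_pd=0.0, noise_cv=0.0)
        series = simulate_trf_series(cfg, seed=1)
        first = series.lanes[0].intensity
        for lane in series.lanes[1:]:
            assert np.allclose(lane.intensity, first)

    def test_mean_arithmetic(self):
        cfg = TRFSimConfig(initial_mean_kb=9.0, shortening_rate_bp_per_pd=150.0, pds=(0.0, 10.0))
        assert cfg.initial_mean_kb - cfg.shortening_rate_bp_per_pd * 10 / 1000 == 7.5

    def test_round_trip_mean_recovery(self):
        cfg = TRFSimConfig(noise_cv=0.02)
        series = simulate_trf_series(cfg, seed=2)
        for lane in series.lanes:
            expected = cfg.initial_mean_kb - cfg.shortening_rate_bp_per_pd * lane.pd_at_sampling / 1000
            got = trf_mean_length(lane, series.ladder)
            assert got == pytest.approx(expected, rel=0.05)

    def test_length_reaching_zero_rejected(self):
        with pytest.raises(ValueError, match="<= 0"):
            TRFSimConfig(initial_mean_kb=2.0, shortening_rate_bp_per_pd=150.0, pds=(0.0, 20.0))
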