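import numpy as np
import pytest

from replistress import (
    average_replicates,
    call_differential,
    genome_fraction,
    loess_smooth,
    make_genome,
    profile_ci,
)
from replistress.profiles import DifferentialRegion, SmoothedRTProfile


def band_profile(lower, upper, chrom=None, spacing=13_000, condition=""):
    """Build a profile directly from band vectors (fit = band midpoint)."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = lower.size
    if chrom is None:
        chrom = np.repeat(np.asarray(["chr1"], dtype=object), n)
    start = np.arange(n, dtype=np.int64) * spacing
    fit = (lower + upper) / 2.0
    return SmoothedRTProfile(
        chrom=np.asarray(chrom, dtype=object),
        start=start,
        end=start + spacing,
        position=(start + spacing).astype(float),
        fit=fit,
        se=(upper - lower) / 4.0,
        level=0.95,
        lower=lower,
        upper=upper,
        condition=condition,
    )


class TestLoessSmooth:
    def test_constant_profile(self):
        pos = np.arange(1, 301) * 13_000.0
        prof = loess_smooth(np.full(300, 1.5), pos, bandwidth=3e6)
        assert np.allclose(prof.fit, 1.5)
        assert np.nanmax(prof.se) < 1e-9
        assert (prof.lower <= prof.fit).all() and (prof.fit <= prof.upper).all()

    def test_linear_exactness(self):
        pos = np.arange(1, 501) * 13_000.0
        y = 0.1 + 3e-8 * pos
        prof = loess_smooth(y, pos, bandwidth=3e6)
        assert np.nanmax(np.abs(prof.fit - y)) < 1e-9

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            loess_smooth(np.zeros(5), np.array([1.0, 3.0, 2.0, 4.0, 5.0]), bandwidth=100.0)

    def test_bandwidth_must_exceed_spacing(self):
        pos = np.arange(1, 100) * 13_000.0
        with pytest.raises(ValueError, match="bandwidth"):
            loess_smooth(np.zeros(99), pos, bandwidth=1_000.0)


class TestAverageReplicates:
    def test_identical_replicates(self):
        pos = np.arange(1, 101) * 13_000.0
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 100)
        p1 = loess_smooth(y, pos, 3e6, condition="c")
        p2 = loess_smooth(y, pos, 3e6, condition="c")
        assert np.allclose(average_replicates([p1, p2]), p1.fit, equal_nan=True)

    def test_probe_wise_mean_and_permutation_invariance(self):
        pos = np.arange(1, 51) * 13_000.0
        profs = []
        for offset in (1.0, 3.0, 5.0):
            profs.append(loess_smooth(np.full(50, offset), pos, 3e6, condition="c"))
        avg = average_replicates(profs)
        assert np.allclose(avg, 3.0)
        assert np.allclose(average_replicates(profs[::-1]), avg)

    def test_grid_mismatch_rejected(self):
        p1 = loess_smooth(np.zeros(50), np.arange(1, 51) * 13_000.0, 3e6)
        p2 = loess_smooth(np.zeros(60), np.arange(1, 61) * 13_000.0, 3e6)
        with pytest.raises(ValueError, match="grid"):
            average_replicates([p1, p2])


class TestProfileCI:
    def test_zero_noise_band_collapses(self):
        pos = np.arange(1, 201) * 13_000.0
        prof = profile_ci(np.full(200, 0.7), pos, bandwidth=3e6)
        assert np.nanmax(prof.upper - prof.lower) < 1e-6

    def test_higher_level_strictly_wider(self):
        pos = np.arange(1, 201) * 13_000.0
        rng = np.random.default_rng(1)
        y = rng.normal(0, 0.3, 200)
        p95 = profile_ci(y, pos, bandwidth=3e6, level=0.95)
        p99 = profile_ci(y, pos, bandwidth=3e6, level=0.99)
        ok = np.isfinite(p95.se) & (p95.se > 0)
        assert (p99.upper[ok] > p95.upper[ok]).all()
        assert (p99.lower[ok] < p95.lower[ok]).all()

    def test_pointwise_coverage_of_flat_truth(self):
        """95% band covers a flat truth 92-98% of the time at interior probes."""
        pos = np.arange(1, 770) * 13_000.0
        interior = (pos > 1.5e6) & (pos < pos[-1] - 1.5e6)
        coverage = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = rng.normal(0.0, 0.3, pos.size)
            prof = profile_ci(y, pos, bandwidth=3e6, level=0.95)
            coverage.append(
                np.mean((prof.lower[interior] <= 0.0) & (0.0 <= prof.upper[interior]))
            )
        assert 0.92 <= np.mean(coverage) <= 0.98


class TestCallDifferential:
    def test_identical_profiles_empty(self):
        pos = np.arange(1, 101) * 13_000.0
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.3, 100)
        p = profile_ci(y, pos, 3e6)
        assert call_differential(p, p) == []

    def test_large_shift_one_region_per_chromosome(self):
        layout = make_genome(2, 2_600_000, 13_000)
        rng = np.random.default_rng(3)
        y = rng.normal(0, 0.1, layout.n_probes)
        ref = profile_ci(y, layout=layout, bandwidth=1e6)
        cond = profile_ci(y + 10.0, layout=layout, bandwidth=1e6)
        regions = call_differential(cond, ref, min_probes=8)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"chr1", "chr2"}
        assert all(r.direction == "earlier" for r in regions)

    def test_direction_flips_under_swap(self):
        rng = np.random.default_rng(4)
        n = 200
        lo1 = rng.normal(0, 1, n)
        lo2 = rng.normal(0, 1, n)
        a = band_profile(lo1, lo1 + 0.5)
        b = band_profile(lo2, lo2 + 0.5)
        fwd = call_differential(a, b, min_probes=3)
        rev = call_differential(b, a, min_probes=3)
        flip = {"earlier": "later", "later": "earlier"}
        assert [(r.chrom, r.start, r.end, r.direction) for r in fwd] == [
            (r.chrom, r.start, r.end, flip[r.direction]) for r in rev
        ]

    def test_matches_brute_force_scan(self):
        """Region calls equal an independent per-probe disjointness scan."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = 120
            c_lo = rng.normal(0, 1, n)
            c_hi = c_lo + rng.uniform(0.1, 1.0, n)
            r_lo = rng.normal(0, 1, n)
            r_hi = r_lo + rng.uniform(0.1, 1.0, n)
            cond = band_profile(c_lo, c_hi)
            ref = band_profile(r_lo, r_hi)
            min_probes = int(rng.integers(1, 5))
            got = [
                (r.chrom, r.start, r.end, r.direction, r.n_probes)
                for r in call_differential(cond, ref, min_probes)
            ]
            # brute force: per-probe interval disjointness then run grouping
            expected = []
            state = []
            for i in range(n):
                if c_hi[i] < r_lo[i] or c_lo[i] > r_hi[i]:
                    state.append(1 if cond.fit[i] > ref.fit[i] else -1)
                else:
                    state.append(0)
            i = 0
            while i < n:
                if state[i] == 0:
                    i += 1
                    continue
                j = i
                while j + 1 < n and state[j + 1] == state[i]:
                    j += 1
                if j - i + 1 >= min_probes:
                    expected.append(
                        (
                            "chr1",
                            i * 13_000,
                            (j + 1) * 13_000,
                            "earlier" if state[i] > 0 else "later",
                            j - i + 1,
                        )
                    )
                i = j + 1
            assert got == expected

    def test_widening_bands_never_adds_calls(self):
        rng = np.random.default_rng(6)
        n = 150
        c_lo = rng.normal(0, 1, n)
        r_lo = rng.normal(0, 1, n)
        narrow_c, narrow_r = band_profile(c_lo, c_lo + 0.4), band_profile(r_lo, r_lo + 0.4)
        wide_c = band_profile(c_lo - 0.2, c_lo + 0.6)
        wide_r = band_profile(r_lo - 0.2, r_lo + 0.6)

        def probes(regions):
            return {
                (r.chrom, p)
                for r in regions
                for p in range(r.start, r.end, 13_000)
            }

        assert probes(call_differential(wide_c, wide_r, 1)) <= probes(
            call_differential(narrow_c, narrow_r, 1)
        )

    def test_regions_sorted_nonoverlapping(self):
        rng = np.random.default_rng(7)
        n = 300
        c_lo = rng.normal(0.3, 0.8, n)
        r_lo = rng.normal(0, 0.8, n)
        regions = call_differential(
            band_profile(c_lo, c_lo + 0.3), band_profile(r_lo, r_lo + 0.3), 2
        )
        for a, b in zip(regions[:-1], regions[1:]):
            assert a.end <= b.start or a.chrom != b.chrom


class TestGenomeFraction:
    def test_no_regions(self):
        layout = make_genome(2, 1_000_000, 13_000)
        table = genome_fraction([], layout)
        assert (table["percent"] == 0.0).all()

    def test_single_region_percent(self):
        layout = make_genome(1, 100_100_000, 13_000)
        covered = layout.covered_length["chr1"]
        region = DifferentialRegion("chr1", 0, covered // 100, "earlier", 1.0, 50)
        table = genome_fraction([region], layout, per_chromosome=True)
        earlier = table[(table.scope == "chr1") & (table.direction == "earlier")]
        assert earlier["percent"].iloc[0] == pytest.approx(1.0)

    def test_region_outside_layout_rejected(self):
        layout = make_genome(1, 1_000_000, 13_000)
        bad = DifferentialRegion("chr9", 0, 100, "earlier", 1.0, 1)
        with pytest.raises(ValueError, match="unknown chromosome"):
            genome_fraction([bad], layout)


class TestRegionInvariants:
    def test_direction_sign_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DifferentialRegion("chr1", 0, 100, "earlier", -1.0, 3)
        with pytest.raises(ValueError):
            DifferentialRegion("chr1", 100, 100, "later", -1.0, 3)

    def test_profile_bound_invariant(self):
        pos = np.arange(1, 21) * 13_000.0
        with pytest.raises(ValueError, match="bracket"):
            SmoothedRTProfile(
                chrom=np.repeat(np.asarray(["chr1"], dtype=object), 20),
                start=(pos - 13_000).astype(np.int64),
                end=pos.astype(np.int64),
                position=pos,
                fit=np.ones(20),
                se=np.ones(20),
                level=0.95,
                lower=np.full(20, 2.0),
                upper=np.full(20, 3.0),
            )
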