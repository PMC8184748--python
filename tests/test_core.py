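"""The caller's statistics: smoothing, permutation nulls, cis correction,
candidate selection, cross-scale grouping, significance."""

import itertools

import numpy as np
import pytest

from pliertlc.core import (
    CandidateCall,
    PlierParams,
    candidate_calls,
    cis_layout,
    cis_residual,
    combine_scales,
    compute_z,
    gaussian_kernel,
    gaussian_smooth,
    integrated_z,
    isotonic_fit,
    null_shuffle,
    null_swap,
    proximity_frequency,
    score_scale,
    significant_calls,
)
from pliertlc.genome import ChromosomeSet, Viewpoint, build_grid, digest_reference
from pliertlc.tlc_io import SegmentCoverage


class TestSmoothing:
    def test_constant_preserved_including_edges(self):
        out = gaussian_smooth(np.full(50, 3.7), sigma=0.75, span=31)
        assert np.allclose(out, 3.7)

    def test_impulse_reproduces_normalized_kernel(self):
        n, span, sigma = 101, 31, 0.75
        x = np.zeros(n)
        x[50] = 1.0
        out = gaussian_smooth(x, sigma, span)
        k = gaussian_kernel(sigma, span)
        assert np.isclose(out[50], k[(span - 1) // 2])
        assert np.allclose(out[50 - 15 : 50 + 16], k)

    def test_all_zero(self):
        assert not gaussian_smooth(np.zeros(20), 0.75, 31).any()

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros(10), 0.75, 30)

    def test_kernel_sums_to_one(self):
        for sigma, span in [(0.5, 11), (0.75, 31), (2.0, 61)]:
            assert np.isclose(gaussian_kernel(sigma, span).sum(), 1.0)


class TestProximityFrequency:
    def test_counts_match_linear_scan(self):
        seq = ("A" * 137 + "CATG") * 300  # segments of 141 bp
        segs = digest_reference({"c1": seq, "c2": seq}, "CATG")
        rng = np.random.default_rng(0)
        support = rng.integers(0, 3, size=segs.n_segments).astype(np.int32)
        cov = SegmentCoverage(segs, support, n_reads=10)
        grid = build_grid(segs.chroms, 5_000)
        f = proximity_frequency(cov, grid)
        # oracle: loop over segments, assign by start coordinate
        expect = np.zeros(grid.n_bins, dtype=int)
        for ci, name in enumerate(segs.chroms.names):
            starts = segs.starts(name)
            covd = support[segs.offsets[ci] : segs.offsets[ci + 1]] > 0
            for s, c in zip(starts, covd):
                if c:
                    expect[grid.offsets[ci] + s // 5_000] += 1
        assert np.array_equal(f, expect)

    def test_straddling_segment_counted_once_in_start_bin(self):
        seq = "A" * 4_900 + "CATG" + "A" * 5_096  # segment [4900, 10000)
        segs = digest_reference({"c": seq}, "CATG")
        support = np.array([0, 1], dtype=np.int32)
        f = proximity_frequency(SegmentCoverage(segs, support, 1), build_grid(segs.chroms, 5_000))
        # the covered segment [4900, 10000) straddles the bin boundary but is
        # counted exactly once, in the bin holding its start coordinate
        assert list(f) == [1, 0]


def identity_stat(F):
    return F


def smooth_stat(F):
    return gaussian_smooth(F, 0.75, 3)


class TestNulls:
    def test_shuffle_matches_exhaustive_enumeration(self):
        # 6-bin pool: enumerate all 720 permutations of f, smooth, and compare
        f = np.array([0.0, 1.0, 2.0, 0.0, 4.0, 1.0])
        pool = np.arange(6)
        stats = np.array(
            [smooth_stat(np.asarray(p, dtype=float)) for p in itertools.permutations(f)]
        )
        mu_exact, sd_exact = stats.mean(axis=0), stats.std(axis=0)
        rng = np.random.default_rng(0)
        mu, sd = null_shuffle(f, pool, 4_000, rng, smooth_stat)
        # CLT tolerance at n_perm = 4000
        assert np.allclose(mu, mu_exact, atol=4 * sd_exact.max() / np.sqrt(4_000))
        assert np.allclose(sd, sd_exact, atol=0.08)

    def test_constant_pool_gives_zero_sd(self):
        f = np.full(10, 2.0)
        mu, sd = null_shuffle(f, np.arange(10), 50, np.random.default_rng(0), smooth_stat)
        assert np.allclose(sd, 0.0)
        assert np.allclose(mu, smooth_stat(f))

    def test_all_zero_track(self):
        mu, sd = null_shuffle(np.zeros(10), np.arange(10), 10, np.random.default_rng(0), smooth_stat)
        assert not mu.any() and not sd.any()

    def test_swap_keeps_zero_bins_zero(self):
        f = np.array([0.0, 3.0, 0.0, 5.0, 0.0, 2.0])
        mu, sd = null_swap(f, np.arange(6), 200, np.random.default_rng(1), identity_stat)
        zero_bins = f == 0
        assert not mu[zero_bins].any() and not sd[zero_bins].any()
        assert mu[~zero_bins].all()

    def test_swap_single_nonzero_gives_zero_z(self):
        f = np.array([0.0, 0.0, 7.0, 0.0])
        mu, sd = null_swap(f, np.arange(4), 50, np.random.default_rng(0), smooth_stat)
        p = smooth_stat(f)
        z, _ = compute_z(p, (p, np.ones_like(p)), (mu, sd))
        # every permutation identical to observed -> no evidence of enrichment
        assert abs(z[2]) < 1e-6

    def test_swap_two_equal_values_permutation_invariant(self):
        f = np.array([0.0, 4.0, 0.0, 4.0])
        _, sd = null_swap(f, np.arange(4), 50, np.random.default_rng(0), smooth_stat)
        assert np.allclose(sd, 0.0)

    def test_swap_degenerate_all_zero(self):
        mu, sd = null_swap(np.zeros(5), np.arange(5), 10, np.random.default_rng(0), smooth_stat)
        assert not mu.any() and not sd.any()

    def test_nperm_and_pool_validation(self):
        with pytest.raises(ValueError):
            null_shuffle(np.ones(4), np.arange(4), 1, np.random.default_rng(0), identity_stat)
        with pytest.raises(ValueError):
            null_shuffle(np.ones(4), np.array([], dtype=int), 10, np.random.default_rng(0), identity_stat)


class TestComputeZ:
    def test_zero_when_observed_equals_expectation(self):
        p = np.array([1.0, 2.0])
        z, _ = compute_z(p, (p, np.ones(2)), (p, np.ones(2)))
        assert np.allclose(z, 0.0)

    def test_minimum_of_the_two_nulls(self):
        p = np.array([10.0])
        sh = (np.array([0.0]), np.array([1.0]))  # z = 10
        sw = (np.array([7.0]), np.array([1.0]))  # z = 3
        z, _ = compute_z(p, sh, sw)
        assert np.isclose(z[0], 3.0)

    def test_sd_floor_yields_finite_z_and_flag(self):
        p = np.array([1.0])
        z, floored = compute_z(p, (np.zeros(1), np.zeros(1)), (np.zeros(1), np.zeros(1)), sd_floor=1e-6)
        assert np.isfinite(z[0]) and floored[0]


def pava_non_increasing(y):
    """Reference pool-adjacent-violators, non-increasing."""
    y = list(map(float, y))
    vals, wts = [], []
    for v in y:
        vals.append(v)
        wts.append(1.0)
        while len(vals) > 1 and vals[-2] < vals[-1]:
            v2 = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / (wts[-1] + wts[-2])
            w2 = wts[-1] + wts[-2]
            vals = vals[:-2] + [v2]
            wts = wts[:-2] + [w2]
    out = []
    for v, w in zip(vals, wts):
        out.extend([v] * int(w))
    return np.asarray(out)


class TestCisCorrection:
    CHROMS = ChromosomeSet(["chr1"], [2_000_000])
    VP = Viewpoint(name="T", chrom="chr1", start=950_000, end=1_050_000)

    def _layout(self, width=5_000):
        grid = build_grid(self.CHROMS, width)
        return grid, cis_layout(self.VP, grid, PlierParams())

    def test_isotonic_equals_pava_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=rng.integers(1, 40))
            assert np.allclose(isotonic_fit(y, increasing=False), pava_non_increasing(y))
            assert np.allclose(
                isotonic_fit(y, increasing=True), pava_non_increasing(y[::-1])[::-1]
            )

    def test_monotone_flank_gives_zero_residual(self):
        grid, layout = self._layout()
        f = np.zeros(grid.n_bins)
        # non-increasing away from the probed region on both flanks
        left = np.linspace(0, 30, layout.mask_lo)
        right = np.linspace(30, 0, layout.n_bins - layout.mask_hi)
        f[: layout.mask_lo] = left
        f[layout.mask_hi :] = right
        res = cis_residual(f, layout, 0.75, 31)
        # smoothing of a monotone ramp stays monotone; the isotonic fit
        # reproduces it, so the residual vanishes off the mask
        assert np.allclose(res[: layout.mask_lo], 0.0, atol=1e-9)
        assert np.allclose(res[layout.mask_hi :], 0.0, atol=1e-9)

    def test_bump_on_decaying_background_leaves_positive_residual(self):
        grid, layout = self._layout()
        f = np.zeros(grid.n_bins)
        n_right = layout.n_bins - layout.mask_hi
        decay = 30 * np.exp(-np.arange(n_right) / 20)
        bump_at = layout.mask_hi + 60
        f[layout.mask_hi :] = decay
        f[bump_at - 2 : bump_at + 3] += 25
        res = cis_residual(f, layout, 0.75, 31)
        assert res[bump_at] > 3
        far = np.r_[res[layout.mask_hi : bump_at - 20], res[bump_at + 20 :]]
        assert np.abs(far).max() < res[bump_at] / 3

    def test_probed_flank_bins_are_masked(self):
        grid, layout = self._layout()
        lo_bp = layout.mask_lo * grid.width
        hi_bp = layout.mask_hi * grid.width
        assert lo_bp <= self.VP.start - 250_000
        assert hi_bp >= self.VP.end + 250_000
        assert layout.mask_lo not in layout.unmasked()

    def test_fit_non_increasing_with_distance_on_every_flank(self):
        grid, layout = self._layout()
        rng = np.random.default_rng(4)
        f = rng.poisson(3, size=grid.n_bins).astype(float)
        sm = gaussian_smooth(f, 0.75, 31)
        left_fit = isotonic_fit(sm[layout.left], increasing=True)
        right_fit = isotonic_fit(sm[layout.right], increasing=False)
        assert (np.diff(left_fit) >= -1e-12).all()
        assert (np.diff(right_fit) <= 1e-12).all()


class TestCandidates:
    CHROMS = ChromosomeSet(["chrA"], [20_000_000])

    def _track(self, z, width=75_000):
        from pliertlc.core import ScoreTrack

        grid = build_grid(self.CHROMS, width)
        full = np.full(grid.n_bins, np.nan)
        full[: len(z)] = z
        return ScoreTrack(
            scale=width,
            grid=grid,
            f=np.zeros(grid.n_bins),
            p=np.zeros(grid.n_bins),
            mu_shuffle=np.zeros(grid.n_bins),
            sd_shuffle=np.ones(grid.n_bins),
            mu_swap=np.zeros(grid.n_bins),
            sd_swap=np.ones(grid.n_bins),
            z=full,
            domain=np.zeros(grid.n_bins, dtype=np.int8),
            callable=np.isfinite(full),
            floored=np.zeros(grid.n_bins, dtype=bool),
        )

    def test_adjacent_bins_merge_with_percentile_integration(self):
        calls = candidate_calls(self._track([6.0, 7.0]), PlierParams())
        assert len(calls) == 1
        assert np.isclose(calls[0].integrated_z, np.percentile([6, 7], 90))

    def test_clusters_two_mb_apart_stay_separate(self):
        z = np.zeros(60)
        z[0:2] = 9.0
        z[29:31] = 9.0  # 27 bins x 75 kb ~ 2 Mb gap
        calls = candidate_calls(self._track(z), PlierParams())
        assert len(calls) == 2

    def test_sub_merge_distance_gap_merges(self):
        z = np.zeros(60)
        z[0] = 9.0
        z[10] = 9.0  # 9-bin gap = 675 kb < 1 Mb
        calls = candidate_calls(self._track(z), PlierParams())
        assert len(calls) == 1

    def test_no_bins_above_threshold_no_calls(self):
        assert candidate_calls(self._track([5.0, 4.0, 3.0]), PlierParams()) == []

    def test_integrated_z_matches_sorted_array_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            v = rng.normal(10, 3, size=rng.integers(1, 25))
            s = np.sort(v)
            rank = 0.9 * (len(s) - 1)
            lo, hi = int(np.floor(rank)), int(np.ceil(rank))
            oracle = s[lo] + (rank - lo) * (s[hi] - s[lo])
            assert np.isclose(integrated_z(v), oracle)


def cand(chrom, start, end, scale, iz):
    return CandidateCall(chrom=chrom, start=start, end=end, scale=scale, bins=[], integrated_z=iz)


class TestCombineScales:
    VP = Viewpoint(name="T", chrom="chr9", start=0, end=1_000)

    def test_largest_scale_supplies_the_enrichment(self):
        calls = combine_scales(
            {5_000: [cand("chr2", 1_000_000, 1_005_000, 5_000, 12.0)],
             75_000: [cand("chr2", 1_500_000, 1_575_000, 75_000, 9.0)]},
            PlierParams(),
            viewpoint=self.VP,
        )
        assert len(calls) == 1
        assert calls[0].enrichment == 9.0
        assert (calls[0].start, calls[0].end) == (1_500_000, 1_575_000)

    def test_missing_counterpart_scale_blocks_the_call(self):
        calls = combine_scales(
            {5_000: [cand("chr2", 0, 5_000, 5_000, 30.0)], 75_000: []},
            PlierParams(),
            viewpoint=self.VP,
        )
        assert calls == []

    def test_weak_small_scale_still_passes_if_selected(self):
        calls = combine_scales(
            {5_000: [cand("chr2", 0, 5_000, 5_000, 5.5)],
             75_000: [cand("chr2", 0, 75_000, 75_000, 20.0)]},
            PlierParams(),
            viewpoint=self.VP,
        )
        assert len(calls) == 1 and calls[0].enrichment == 20.0

    def test_groups_beyond_group_distance_split(self):
        calls = combine_scales(
            {5_000: [cand("chr2", 0, 5_000, 5_000, 6.0)],
             75_000: [cand("chr2", 15_000_000, 15_075_000, 75_000, 9.0)]},
            PlierParams(),
            viewpoint=self.VP,
        )
        assert calls == []  # 15 Mb apart: two incomplete groups

    def test_multiple_largest_members_take_max_and_union(self):
        calls = combine_scales(
            {5_000: [cand("chr2", 0, 5_000, 5_000, 6.0)],
             75_000: [cand("chr2", 0, 75_000, 75_000, 9.0),
                      cand("chr2", 2_000_000, 2_075_000, 75_000, 11.0)]},
            PlierParams(),
            viewpoint=self.VP,
        )
        assert len(calls) == 1
        assert calls[0].enrichment == 11.0
        assert (calls[0].start, calls[0].end) == (0, 2_075_000)
        assert "multiple_largest_scale_members" in calls[0].flags

    def test_cis_class_by_chromosome(self):
        calls = combine_scales(
            {5_000: [cand("chr9", 5_000_000, 5_005_000, 5_000, 20.0)],
             75_000: [cand("chr9", 5_000_000, 5_075_000, 75_000, 20.0)]},
            PlierParams(),
            viewpoint=self.VP,
        )
        assert calls[0].kind == "cis"


class TestSignificance:
    VP = Viewpoint(name="T", chrom="chr9", start=0, end=1_000)

    def _one(self, chrom, enr):
        calls = combine_scales(
            {5_000: [cand(chrom, 0, 5_000, 5_000, enr)],
             75_000: [cand(chrom, 0, 75_000, 75_000, enr)]},
            PlierParams(),
            viewpoint=self.VP,
        )
        return significant_calls(calls, PlierParams())[0]

    def test_trans_threshold_inclusive_at_eight(self):
        assert self._one("chr2", 8.5).significant
        assert self._one("chr2", 8.0).significant
        assert not self._one("chr2", 7.9).significant

    def test_cis_needs_more_than_sixteen(self):
        assert not self._one("chr9", 12.0).significant
        assert not self._one("chr9", 16.0).significant
        assert self._one("chr9", 16.1).significant


class TestScoreScale:
    def test_cis_exclusion_zone_not_callable(self):
        chroms = ChromosomeSet(["chr1", "chr2"], [12_000_000, 5_000_000])
        seq_segments = digest_reference(
            {"chr1": ("A" * 137 + "CATG") * (12_000_000 // 141 + 1),
             "chr2": ("A" * 137 + "CATG") * (5_000_000 // 141 + 1)},
            "CATG",
        )
        # fabricate coverage with a strong cis pile 2 Mb from the viewpoint
        vp = Viewpoint(name="T", chrom="chr1", start=5_900_000, end=6_100_000)
        support = np.zeros(seq_segments.n_segments, dtype=np.int32)
        b = seq_segments.boundaries["chr1"]
        pile = (b[:-1] >= 8_000_000) & (b[:-1] < 8_050_000)  # ~1.9 Mb from envelope
        support[: len(pile)][pile] = 5
        cov = SegmentCoverage(seq_segments, support, 100)
        params = PlierParams(n_perm=20, seed=1)
        tr = score_scale(cov, vp, 75_000, params)
        sl = tr.grid.chrom_slice("chr1")
        bin_of_pile = sl.start + 8_000_000 // 75_000
        assert not tr.callable[bin_of_pile]  # inside the +- 3 Mb exclusion
        far_bin = sl.start + 11_000_000 // 75_000
        assert tr.callable[far_bin]

    def test_deterministic_given_seed(self, rearranged_library, small_segments):
        cfg, rs, _ = rearranged_library
        from pliertlc.tlc_io import segment_coverage

        cov = segment_coverage(rs.mapped(0), small_segments)
        params = PlierParams(n_perm=30, seed=9)
        a = score_scale(cov, cfg.viewpoints[0], 75_000, params)
        b = score_scale(cov, cfg.viewpoints[0], 75_000, params)
        finite = np.isfinite(a.z)
        assert np.array_equal(finite, np.isfinite(b.z))
        assert np.allclose(a.z[finite], b.z[finite])
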