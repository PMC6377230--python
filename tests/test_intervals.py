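"""Overlap counting, randomization, Monte Carlo tests, closest+Fisher."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tadakit.intervals import (
    StepSignal,
    closest_fisher,
    mc_overlap,
    mc_signal_ratio,
    mean_signal_at,
    overlap,
    random_peakset,
)
from tadakit.peaks import PeakSet

from .conftest import make_peakset
from .oracles import (
    base_array_signal,
    fisher_two_sided,
    naive_overlap_flags,
    naive_window_mean,
)

LENGTHS = {"chr1": 200_000, "chr2": 150_000}


def _ps(intervals, chrom="chr1", name="p"):
    starts, ends = zip(*intervals)
    return PeakSet(
        name=name,
        chrom=np.full(len(intervals), chrom, dtype=object),
        start=np.array(starts),
        end=np.array(ends),
    )


def _random_signal(rng, lengths=LENGTHS, n_seg=400):
    intervals = {}
    for chrom, L in lengths.items():
        edges = np.sort(rng.choice(np.arange(1, L), n_seg, replace=False))
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [L]])
        # leave occasional gaps (absent signal = 0)
        keep = rng.random(starts.size) < 0.85
        intervals[chrom] = (
            starts[keep], ends[keep], rng.normal(1.0, 2.0, keep.sum())
        )
    return StepSignal(intervals, lengths)


class TestOverlap:
    def test_identical_sets_fully_overlap(self):
        a = _ps([(10, 50), (100, 150)])
        res = overlap(a, a)
        assert res.frac_a == 1.0 and res.frac_b == 1.0

    def test_disjoint_sets_do_not_overlap(self):
        a = _ps([(10, 50)])
        b = _ps([(50, 90)])  # bookended, half-open: no shared base
        res = overlap(a, b)
        assert res.a_overlapping_b == 0 and res.b_overlapping_a == 0

    def test_single_base_overlap_counts(self):
        a = _ps([(10, 51)])
        b = _ps([(50, 90)])
        res = overlap(a, b)
        assert res.a_overlapping_b == 1 and res.b_overlapping_a == 1

    def test_matches_quadratic_oracle_on_random_sets(self):
        rng = np.random.default_rng(41)
        a = make_peakset(rng, 10_000, LENGTHS, min_len=50, max_len=800, name="a")
        b = make_peakset(rng, 1000, LENGTHS, min_len=50, max_len=800, name="b")
        res = overlap(a, b)
        a_list = list(zip(a.chrom.astype(str), a.start.tolist(), a.end.tolist()))
        b_list = list(zip(b.chrom.astype(str), b.start.tolist(), b.end.tolist()))
        assert res.a_overlapping_b == sum(naive_overlap_flags(a_list, b_list))
        assert res.b_overlapping_a == sum(naive_overlap_flags(b_list, a_list))


class TestRandomPeakset:
    def test_forced_placement_on_tight_chromosome(self):
        ref = _ps([(0, 100)])
        rand = random_peakset(ref, {"chr1": 100}, seed=1)
        assert (int(rand.start[0]), int(rand.end[0])) == (0, 100)

    def test_preserves_per_chromosome_length_multisets(self):
        rng = np.random.default_rng(42)
        ref = make_peakset(rng, 300, LENGTHS, name="ref")
        for seed in range(20):
            rand = random_peakset(ref, LENGTHS, seed=seed)
            for chrom in LENGTHS:
                ref_lens = sorted((ref.end - ref.start)[ref.chrom == chrom])
                rand_lens = sorted((rand.end - rand.start)[rand.chrom == chrom])
                assert ref_lens == rand_lens

    def test_peak_longer_than_chromosome_rejected(self):
        ref = _ps([(0, 500)])
        with pytest.raises(ValueError):
            random_peakset(ref, {"chr1": 400}, seed=0)

    def test_start_positions_uniform_by_chisquare(self):
        # one 100-bp peak on a 1000-bp chromosome: start uniform on [0, 900]
        ref = _ps([(0, 100)])
        starts = [
            int(random_peakset(ref, {"chr1": 1000}, seed=s).start[0])
            for s in range(10_000)
        ]
        bins = np.histogram(starts, bins=10, range=(0, 901))[0]
        chi2 = ((bins - 1000.0) ** 2 / 1000.0).sum()
        p = stats.chi2.sf(chi2, df=9)
        assert p > 0.01

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(43)
        ref = make_peakset(rng, 50, LENGTHS)
        r1 = random_peakset(ref, LENGTHS, seed=99)
        r2 = random_peakset(ref, LENGTHS, seed=99)
        assert np.array_equal(r1.start, r2.start)


class TestMcOverlap:
    def test_genome_covering_reference_degenerates(self):
        a = _ps([(100, 200), (5000, 5400)])
        b = _ps([(0, 200_000)])
        res = mc_overlap(a, b, {"chr1": 200_000}, n_iter=50, seed=3)
        assert res.degenerate
        assert res.observed == 1.0
        assert res.empirical_p == 1.0
        assert res.parametric_p is None

    def test_jittered_copy_is_extreme(self):
        rng = np.random.default_rng(44)
        a = make_peakset(rng, 200, {"chr1": 10_000_000}, min_len=300,
                         max_len=1500, name="a")
        jitter = rng.integers(-100, 101, len(a))
        b = PeakSet(name="b", chrom=a.chrom.copy(), start=a.start + jitter,
                    end=a.end + jitter)
        res = mc_overlap(a, b, {"chr1": 10_000_000}, n_iter=100, seed=4)
        assert res.parametric_p < 1e-10
        assert res.empirical_p == pytest.approx(1 / 101)

    def test_seed_determinism_and_null_stability(self):
        rng = np.random.default_rng(45)
        a = make_peakset(rng, 100, LENGTHS, name="a")
        b = make_peakset(rng, 100, LENGTHS, name="b")
        r1 = mc_overlap(a, b, LENGTHS, n_iter=100, seed=5)
        r2 = mc_overlap(a, b, LENGTHS, n_iter=100, seed=5)
        assert r1.to_dict() == r2.to_dict()
        r3 = mc_overlap(a, b, LENGTHS, n_iter=100, seed=6)
        se = np.hypot(r1.null_sd, r3.null_sd) / np.sqrt(100)
        assert abs(r1.null_mean - r3.null_mean) < 3 * se


class TestMeanSignalAt:
    def test_constant_signal_gives_constant_means(self):
        sig = StepSignal(
            {"chr1": (np.array([0]), np.array([200_000]), np.array([2.0]))},
            {"chr1": 200_000},
        )
        regions = _ps([(1000, 1400), (50_000, 50_600)])
        means, grand = mean_signal_at(regions, sig, half_width=2000)
        assert np.allclose(means, 2.0)
        assert grand == pytest.approx(2.0)

    def test_half_covered_window_averages_to_half(self):
        # signal 1.0 on exactly the left half of the 4-kb window
        sig = StepSignal(
            {"chr1": (np.array([8000]), np.array([10_000]), np.array([1.0]))},
            {"chr1": 200_000},
        )
        regions = _ps([(9950, 10_050)])  # center 10_000, window [8000, 12000)
        means, _ = mean_signal_at(regions, sig, half_width=2000)
        assert means[0] == pytest.approx(0.5)

    def test_matches_base_resolution_oracle(self):
        rng = np.random.default_rng(46)
        sig = _random_signal(rng)
        regions = make_peakset(rng, 10_000, LENGTHS, min_len=100,
                               max_len=900, name="r")
        means, grand = mean_signal_at(regions, sig, half_width=2000)
        base = {
            chrom: base_array_signal(*sig._data[chrom][:3], LENGTHS[chrom])
            for chrom in LENGTHS
        }
        centers = regions.centers
        for i in range(len(regions)):
            chrom = str(regions.chrom[i])
            exp = naive_window_mean(
                base[chrom], int(centers[i]) - 2000, int(centers[i]) + 2000
            )
            assert means[i] == pytest.approx(exp, abs=1e-9)


class TestMcSignalRatio:
    def test_identical_sets_give_unit_ratio(self):
        rng = np.random.default_rng(47)
        sig = _random_signal(rng)
        a = make_peakset(rng, 50, LENGTHS, name="a")
        res = mc_signal_ratio(sig, a, a, n_iter=20, seed=8)
        assert res.observed == pytest.approx(1.0)
        assert res.extra["difference"] == pytest.approx(0.0)

    def test_swapping_sets_inverts_ratio(self):
        rng = np.random.default_rng(48)
        sig = _random_signal(rng)
        a = make_peakset(rng, 40, LENGTHS, name="a")
        b = make_peakset(rng, 40, LENGTHS, name="b")
        r_ab = mc_signal_ratio(sig, a, b, n_iter=10, seed=9)
        r_ba = mc_signal_ratio(sig, b, a, n_iter=10, seed=9)
        assert r_ab.observed == pytest.approx(1 / r_ba.observed)

    def test_constructed_enrichment_is_extreme(self):
        # signal elevated only inside A's windows on a flat background
        rng = np.random.default_rng(49)
        lengths = {"chr1": 5_000_000}
        # A peaks on a regular grid so their +-2 kb windows are disjoint
        a_starts = 10_000 + 45_000 * np.arange(100)
        a = _ps([(int(s), int(s) + 500) for s in a_starts], name="a")
        b = make_peakset(rng, 100, lengths, min_len=400, max_len=600, name="b")
        fold = 6.0
        centers = a.centers
        sig = StepSignal(
            {"chr1": (centers - 2000, centers + 2000,
                      np.full(len(a), fold))},
            lengths,
        )
        res = mc_signal_ratio(sig, a, b, n_iter=200, seed=10)
        assert res.parametric_p < 1e-6
        assert res.observed >= fold / 2  # b windows mostly see background 0

    def test_zero_denominator_reports_difference_only(self):
        lengths = {"chr1": 100_000}
        sig = StepSignal(
            {"chr1": (np.array([0]), np.array([1000]), np.array([3.0]))},
            lengths,
        )
        a = _ps([(0, 500)])
        b = _ps([(90_000, 90_500)])  # window sees only absent signal
        res = mc_signal_ratio(sig, a, b, n_iter=20, seed=11)
        assert res.degenerate
        assert np.isnan(res.observed)
        assert res.extra["difference"] > 0


class TestClosestFisher:
    def test_balanced_table_gives_p_one(self):
        # 5/10 within for both query sets
        ref = _ps([(i * 10_000, i * 10_000 + 100) for i in range(5)])
        near = [(i * 10_000 + 300, i * 10_000 + 500) for i in range(5)]
        far = [(i * 10_000 + 5000, i * 10_000 + 5200) for i in range(5)]
        a = _ps(near + far)
        b = _ps(near + far)
        res = closest_fisher(a, b, ref, distance=2000)
        assert res.table == ((5, 5), (5, 5))
        assert res.fisher_p == pytest.approx(1.0)

    def test_center_inside_reference_has_distance_zero(self):
        ref = _ps([(1000, 2000)])
        a = _ps([(1400, 1600)])
        res = closest_fisher(a, a, ref, distance=0)
        assert res.distances_a[0] == 0

    def test_genome_covering_reference_gives_p_one(self):
        ref = _ps([(0, 200_000)])
        rng = np.random.default_rng(50)
        a = make_peakset(rng, 20, {"chr1": 200_000}, name="a")
        b = make_peakset(rng, 30, {"chr1": 200_000}, name="b")
        res = closest_fisher(a, b, ref)
        assert res.within_a == 20 and res.within_b == 30
        assert res.fisher_p == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration_oracle(self):
        ref = _ps([(i * 10_000, i * 10_000 + 100) for i in range(10)])
        a = _ps([(i * 10_000 + 200, i * 10_000 + 400) for i in range(10)])
        b = _ps([(i * 10_000 + 5000, i * 10_000 + 5200) for i in range(10)])
        res = closest_fisher(a, b, ref, distance=2000)
        assert res.table == ((10, 0), (0, 10))
        assert res.fisher_p == pytest.approx(
            fisher_two_sided(((10, 0), (0, 10))), rel=1e-12
        )

    def test_distances_match_bedtools_style_scan(self):
        ref = _ps([(1000, 1200), (5000, 5600)])
        a = _ps([(1300, 1500), (4000, 4200), (800, 900), (7000, 7100)])
        res = closest_fisher(a, a, ref, distance=2000)
        # peaks are coordinate-sorted; centers 850, 1400, 4100, 7050
        # against the edges of [1000,1200) and [5000,5600)
        assert res.distances_a.tolist() == [
            1000 - 850, 1400 - 1199, 5000 - 4100, 7050 - 5599,
        ]


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
)
def test_fisher_symmetric_under_row_and_column_swap(a, b, c, d):
    """Swapping both rows and columns leaves the Fisher p unchanged."""
    p1 = fisher_two_sided(((a, b), (c, d)))
    p2 = fisher_two_sided(((d, c), (b, a)))
    assert p1 == pytest.approx(p2, rel=1e-9)
    got = stats.fisher_exact([[a, b], [c, d]])[1]
    assert got == pytest.approx(p1, rel=1e-9)
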