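import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tescan.annotation_io import GeneModel
from tescan.enrichment import (
    classify_enhancer_like,
    downsample_to_match,
    log2_enrichment,
    make_bins,
    overlap_fisher,
    promoter_enrichment,
    promoter_interval,
    te_rpkm,
)


class TestMakeBins:
    def test_enumeration_5kb(self):
        grid = make_bins({"chr1": 5000})["chr1"]
        assert grid.intervals() == [
            (0, 2000),
            (1000, 3000),
            (2000, 4000),
            (3000, 5000),
            (4000, 5000),
        ]

    def test_enumeration_2kb(self):
        grid = make_bins({"chr1": 2000})["chr1"]
        assert grid.intervals() == [(0, 2000), (1000, 2000)]

    def test_short_chromosome_single_truncated_bin(self):
        grid = make_bins({"chr1": 500})["chr1"]
        assert grid.intervals() == [(0, 500)]

    def test_consecutive_starts_differ_by_step(self):
        grid = make_bins({"chr1": 123_456})["chr1"]
        starts = grid.starts()
        assert np.all(np.diff(starts) == 1000)
        assert starts[-1] < 123_456

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            make_bins({"chr1": 0})


class TestDownsample:
    def test_equal_totals_identity(self):
        a = np.array([10, 20, 30])
        merged = downsample_to_match([a.copy(), a.copy()], seed=0)
        assert merged.sum() == 2 * a.sum()
        assert (merged >= a).all()  # nothing was thinned

    def test_unequal_totals_thinned_to_match(self):
        rng = np.random.default_rng(5)
        big = rng.poisson(200, size=10_000)  # total ~ 2,000,000
        small = rng.poisson(100, size=10_000)  # total ~ 1,000,000
        merged = downsample_to_match([big, small], seed=1)
        thinned_big = merged.sum() - small.sum()
        sd = np.sqrt(big.sum() * 0.5 * 0.5)
        assert abs(thinned_big - small.sum()) <= 3 * sd

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        reps = [rng.poisson(50, 1000), rng.poisson(30, 1000)]
        a = downsample_to_match([r.copy() for r in reps], seed=9)
        b = downsample_to_match([r.copy() for r in reps], seed=9)
        assert np.array_equal(a, b)

    def test_zero_total_replicate_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            downsample_to_match([np.array([1, 2]), np.zeros(2, dtype=int)])


class TestTERpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (30, 2000, 1_000_000, 15.0),
            (0, 1234, 1_000_000, 0.0),
            (10, 500, 2_000_000, 10.0),
        ],
    )
    def test_printed_formula(self, count, length, total, expected):
        assert te_rpkm(count, length, total) == pytest.approx(expected, rel=1e-12)

    def test_zero_bin_total_rejected(self):
        with pytest.raises(ValueError):
            te_rpkm(1, 1000, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        count=st.integers(min_value=0, max_value=10_000),
        length=st.integers(min_value=1, max_value=100_000),
        total=st.integers(min_value=1, max_value=10**8),
        k=st.integers(min_value=2, max_value=7),
    )
    def test_linear_in_count_inverse_in_length_and_total(self, count, length, total, k):
        base = te_rpkm(count, length, total)
        assert te_rpkm(k * count, length, total) == pytest.approx(k * base, rel=1e-9)
        assert te_rpkm(count, k * length, total) == pytest.approx(base / k, rel=1e-9)
        assert te_rpkm(count, length, k * total) == pytest.approx(base / k, rel=1e-9)


class TestLog2Enrichment:
    def test_equal_inputs_zero(self):
        assert log2_enrichment(3.7, 3.7) == 0

    def test_printed_value(self):
        assert log2_enrichment(15.0, 2.5) == pytest.approx(np.log2(15.5 / 3.0), rel=1e-12)
        assert log2_enrichment(15.0, 2.5) == pytest.approx(2.36923, abs=1e-5)

    def test_pseudocount_floor_at_zero(self):
        assert log2_enrichment(0.0, 0.0) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
    )
    def test_antisymmetric_under_swap(self, a, b):
        assert log2_enrichment(a, b) == pytest.approx(-log2_enrichment(b, a), abs=1e-9)


class TestClassifyEnhancerLike:
    @pytest.mark.parametrize(
        "score,expected", [(1.50, True), (1.49, False), (-0.2, False), (5.0, True)]
    )
    def test_threshold_inclusive(self, score, expected):
        assert classify_enhancer_like(np.array([score]))[0] == expected

    def test_monotone_in_score(self):
        scores = np.linspace(-3, 4, 101)
        flags = classify_enhancer_like(scores)
        assert np.all(np.diff(flags.astype(int)) >= 0)

    def test_other_marks_never_enhancer(self):
        assert not classify_enhancer_like(np.array([10.0]), mark="H3K9me3")[0]


class TestPromoter:
    def test_plus_strand_window_and_bin(self):
        g = GeneModel("g", "chr1", 10_000, "+", 10_000, 15_000)
        assert promoter_interval(g) == (8_000, 10_500)
        grids = make_bins({"chr1": 50_000})
        chip = {"chr1": np.zeros(grids["chr1"].n_bins)}
        chip["chr1"][8] = 40  # bin [8000,10000): overlap 2000, the maximum
        out = promoter_enrichment([g], grids, chip, {"chr1": np.ones(grids["chr1"].n_bins)}, 1e6, 1e6)
        assert out.loc["g", "bin_index"] == 8

    def test_minus_strand_window_and_bin(self):
        g = GeneModel("g", "chr1", 10_000, "-", 5_000, 10_001)
        assert promoter_interval(g) == (9_500, 12_000)
        grids = make_bins({"chr1": 50_000})
        zeros = {"chr1": np.zeros(grids["chr1"].n_bins)}
        out = promoter_enrichment([g], grids, zeros, zeros, 1e6, 1e6)
        assert out.loc["g", "bin_index"] == 10  # bin [10000,12000), overlap 2000

    def test_tss_at_origin_clipped(self):
        g = GeneModel("g", "chr1", 0, "+", 0, 5_000)
        with pytest.warns(UserWarning, match="clipped"):
            assert promoter_interval(g, 50_000) == (0, 500)
            grids = make_bins({"chr1": 50_000})
            zeros = {"chr1": np.zeros(grids["chr1"].n_bins)}
            promoter_enrichment([g], grids, zeros, zeros, 1e6, 1e6)


def _fisher_oracle(n11, n10, n01, n00):
    """Two-sided exact p by hypergeometric enumeration."""
    N = n11 + n10 + n01 + n00
    K = n11 + n10  # size of set a
    n = n11 + n01  # size of set b
    rv = stats.hypergeom(N, K, n)
    p_obs = rv.pmf(n11)
    ks = np.arange(max(0, K + n - N), min(K, n) + 1)
    return float(rv.pmf(ks)[rv.pmf(ks) <= p_obs * (1 + 1e-7)].sum())


class TestOverlapFisher:
    def _sets(self, n11, n10, n01, n00):
        universe = {f"x{i}" for i in range(n11 + n10 + n01 + n00)}
        items = sorted(universe)
        a = set(items[: n11 + n10])
        b = set(items[:n11]) | set(items[n11 + n10 : n11 + n10 + n01])
        return a, b, universe

    def test_independent_table_is_null(self):
        a, b, u = self._sets(10, 10, 10, 10)
        odds, p = overlap_fisher(a, b, u)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        for table in [(9, 1, 1, 9), (5, 0, 3, 12), (2, 8, 7, 3)]:
            a, b, u = self._sets(*table)
            _, p = overlap_fisher(a, b, u)
            assert p == pytest.approx(_fisher_oracle(*table), abs=1e-12)

    def test_degenerate_margin(self):
        u = {f"x{i}" for i in range(20)}
        b = set(sorted(u)[:5])
        _, p = overlap_fisher(set(u), b, u)  # a == universe
        assert p == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        a, b, u = self._sets(5, 0, 3, 12)
        odds, _ = overlap_fisher(a, b, u)
        assert odds == pytest.approx((5.5 * 12.5) / (0.5 * 3.5))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_fisher(set(), set(), set())
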