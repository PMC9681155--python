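import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tescan.annotation_io import GeneModel, SampleSheet, TELocus
from tescan.linkage import (
    condition_log2_ratio,
    link_nearby_genes,
    linkage_summary,
    spearman,
    tss_distance,
    window_of,
)
from tescan.quantify import ExpressionTable


def _locus(start=100_000, end=105_000, chrom="chr1", lid="L"):
    return TELocus(lid, chrom, start, end, "+", "RLTR45-int", "ERVK", "LTR")


def _gene(tss, gid="G", chrom="chr1"):
    return GeneModel(gid, chrom, tss, "+", tss, tss + 1000)


class TestDistanceAndWindows:
    def test_distance_to_nearest_boundary(self):
        assert tss_distance(_locus(), 140_000) == 35_000
        assert window_of(35_000) == "kb5_50"

    def test_tss_inside_locus_excluded(self):
        assert tss_distance(_locus(), 103_000) == 0
        assert window_of(0) is None

    def test_far_tss_excluded(self):
        assert tss_distance(_locus(), 310_000) == 205_000
        assert window_of(205_000) is None

    @pytest.mark.parametrize(
        "d,expected",
        [
            (4_999, None),
            (5_000, "kb5_50"),
            (50_000, "kb5_50"),  # the shared boundary belongs to the near window
            (50_001, "kb50_200"),
            (200_000, "kb50_200"),
            (200_001, None),
        ],
    )
    def test_window_boundaries(self, d, expected):
        assert window_of(d) == expected

    def test_upstream_and_downstream_both_link(self):
        loci = [_locus()]
        genes = [_gene(140_000, "down"), _gene(70_000, "up")]
        pairs = link_nearby_genes(loci, genes)
        assert {p.gene_id for p in pairs} == {"down", "up"}
        assert all(p.window == "kb5_50" for p in pairs)

    def test_many_to_many_pairs(self):
        loci = [_locus(lid="A"), _locus(start=200_000, end=201_000, lid="B")]
        genes = [_gene(160_000)]
        pairs = link_nearby_genes(loci, genes)
        assert {(p.locus_id, p.gene_id) for p in pairs} == {("A", "G"), ("B", "G")}

    def test_reflection_symmetry(self):
        # reflecting all coordinates of the chromosome preserves the pairing
        L = 1_000_000
        loci = [_locus(100_000, 105_000, lid="A")]
        genes = [_gene(140_000), _gene(10_000, "far")]
        r_loci = [
            TELocus("A", "chr1", L - 105_000, L - 100_000, "+", "RLTR45-int", "ERVK", "LTR")
        ]
        r_genes = [
            GeneModel("G", "chr1", L - 140_000, "+", L - 140_000, L - 139_000),
            GeneModel("far", "chr1", L - 10_000, "+", L - 10_000, L - 9_000),
        ]
        fwd = {(p.locus_id, p.gene_id, p.distance, p.window) for p in link_nearby_genes(loci, genes)}
        rev = {
            (p.locus_id, p.gene_id, p.distance, p.window)
            for p in link_nearby_genes(r_loci, r_genes)
        }
        assert fwd == rev

    def test_emitted_distances_respect_window_bounds(self, default_sim):
        pairs = link_nearby_genes(default_sim["loci"], default_sim["genes"])
        assert pairs, "synthetic annotation should produce linkage pairs"
        for p in pairs:
            if p.window == "kb5_50":
                assert 5_000 <= p.distance <= 50_000
            else:
                assert 50_000 < p.distance <= 200_000

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(tss=st.integers(min_value=0, max_value=500_000))
    def test_window_assignment_consistent_with_distance(self, tss):
        locus = _locus()
        d = tss_distance(locus, tss)
        w = window_of(d)
        pairs = link_nearby_genes([locus], [_gene(tss)])
        if w is None:
            assert pairs == []
        else:
            assert pairs[0].window == w and pairs[0].distance == d


class TestConditionRatio:
    def _fixture(self):
        expr = ExpressionTable(
            pd.DataFrame(
                {"i1": [4.5, 1.0], "i2": [4.5, 1.0], "s1": [9.5, 1.0], "s2": [9.5, 1.0]},
                index=["f1", "f2"],
            ),
            unit="TPM",
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {"sample_id": ["i1", "i2", "s1", "s2"], "condition": ["IVF"] * 2 + ["SCNT"] * 2}
            )
        )
        return expr, sheet

    def test_pseudocount_ratio(self):
        expr, sheet = self._fixture()
        # means 9.5 vs 4.5 with c=0.5 -> log2(10/5) = 1
        assert condition_log2_ratio(expr, sheet, "f1") == pytest.approx(1.0, rel=1e-12)

    def test_equal_means_zero(self):
        expr, sheet = self._fixture()
        assert condition_log2_ratio(expr, sheet, "f2") == 0

    def test_zero_means_zero(self):
        expr = ExpressionTable(
            pd.DataFrame({"i1": [0.0], "i2": [0.0], "s1": [0.0], "s2": [0.0]}, index=["f"]),
            unit="TPM",
        )
        _, sheet = self._fixture()
        assert condition_log2_ratio(expr, sheet, "f") == 0

    def test_unknown_feature_errors(self):
        expr, sheet = self._fixture()
        with pytest.raises(KeyError):
            condition_log2_ratio(expr, sheet, "ghost")


def _rank_oracle(v):
    """Mid-ranks by explicit tie grouping (independent of scipy.rankdata)."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestSpearman:
    def test_monotone_is_one(self):
        r = spearman([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert r.rho == 1.0 and r.p == 0.0

    def test_reversed_is_minus_one(self):
        r = spearman([1, 2, 3, 4, 5], [30, 16, 9, 4, 2])
        assert r.rho == -1.0 and r.p == 0.0

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            if rng.random() < 0.4:  # exercise ties
                x = np.round(x)
            r = spearman(x, y)
            expected = _pearson_oracle(_rank_oracle(x), _rank_oracle(y))
            assert r.rho == pytest.approx(expected, abs=1e-12)

    def test_p_uses_t_approximation(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = spearman(x, y)
        from scipy import stats

        t = r.rho * np.sqrt((r.n - 2) / (1 - r.rho**2))
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t), r.n - 2), rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestLinkageSummary:
    def _pairs(self):
        from tescan.linkage import LinkagePair

        return [
            LinkagePair("A", "g1", 10_000, "kb5_50"),
            LinkagePair("B", "g1", 20_000, "kb5_50"),
            LinkagePair("C", "g1", 30_000, "kb5_50"),
            LinkagePair("D", "g1", 100_000, "kb50_200"),
        ]

    def test_distinct_genes_per_window(self):
        out = linkage_summary(self._pairs())
        near = out[(out.subset == "all") & (out.window == "kb5_50")].iloc[0]
        assert near.n_genes == 1  # three pairs share one gene

    def test_gene_counted_once_per_window(self):
        out = linkage_summary(self._pairs())
        far = out[(out.subset == "all") & (out.window == "kb50_200")].iloc[0]
        assert far.n_genes == 1  # same gene, second window

    def test_empty_pairs(self):
        out = linkage_summary([])
        assert out.empty


class TestPlantedCorrelation:
    def test_positive_rho_with_transfer_slope(self, default_sim):
        from tescan.quantify import compute_tpm

        truth, cfg = default_sim["truth"], default_sim["cfg"]
        te_tpm = compute_tpm(default_sim["te_counts"])
        gene_tpm = compute_tpm(default_sim["gene_counts"])
        sheet = default_sim["sheet"]
        x = [condition_log2_ratio(te_tpm, sheet, l) for (l, g, s) in truth.linked_pairs]
        y = [condition_log2_ratio(gene_tpm, sheet, g) for (l, g, s) in truth.linked_pairs]
        assert len(x) >= 40
        r = spearman(x, y)
        assert r.rho > 0 and r.p < 0.01

    def test_null_slope_rho_near_zero(self):
        from tescan.quantify import compute_tpm
        from tescan.synthetic import SimConfig, simulate_annotation, simulate_rnaseq

        n_small = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, linkage_slope=0.0)
            loci, genes, truth = simulate_annotation(cfg)
            te, gm, sheet = simulate_rnaseq(truth, cfg, loci, genes)
            te_tpm, gene_tpm = compute_tpm(te), compute_tpm(gm)
            x = [condition_log2_ratio(te_tpm, sheet, l) for (l, g, s) in truth.linked_pairs]
            y = [condition_log2_ratio(gene_tpm, sheet, g) for (l, g, s) in truth.linked_pairs]
            if abs(spearman(x, y).rho) < 0.3:
                n_small += 1
        assert n_small >= 0.95 * n_seeds
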