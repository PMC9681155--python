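"""Knockout-validation analysis.

Embryos injected with gRNA/Cas9 against a TE-containing region are
genotyped from expression alone: an embryo is called homozygous knockout
when both targeted loci are essentially silent (TPM < 5). Adjacent genes
are then compared between the knockout and remaining (+/+, +/-) embryos,
the knockout fold changes are correlated with the SCNT/IVF fold changes
of the same genes, and litter genotype counts are tested against the
Mendelian 1:2:1 expectation of a het x het cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import CorrelationResult, spearman
from .quantify import PSEUDOCOUNT, ExpressionTable, welch_t_test

KO_TPM_CUT = 5.0


@dataclass(frozen=True)
class KOCall:
    embryo_id: str
    locus1_tpm: float
    locus2_tpm: float
    genotype: str  # "hom_ko" | "other"


@dataclass(frozen=True)
class GenotypeCounts:
    n_wt: int
    n_het: int
    n_hom: int

    @property
    def total(self) -> int:
        return self.n_wt + self.n_het + self.n_hom


def call_homozygous_ko(
    tpm_table: ExpressionTable,
    target_locus_ids: tuple[str, str],
    tpm_cut: float = KO_TPM_CUT,
) -> list[KOCall]:
    """hom_ko iff both target loci are strictly below the TPM cut (default 5)."""
    l1, l2 = target_locus_ids
    for lid in (l1, l2):
        if lid not in tpm_table.values.index:
            raise KeyError(f"target locus {lid!r} absent from the expression table")
    calls = []
    for emb in tpm_table.sample_ids:
        t1 = float(tpm_table.values.at[l1, emb])
        t2 = float(tpm_table.values.at[l2, emb])
        genotype = "hom_ko" if (t1 < tpm_cut and t2 < tpm_cut) else "other"
        calls.append(KOCall(emb, t1, t2, genotype))
    return calls


def compare_adjacent_genes(
    expr: ExpressionTable,
    calls: list[KOCall],
    gene_ids: list[str],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 ratio (hom_ko over other) and Welch two-tailed t-test on TPM."""
    hom = [c.embryo_id for c in calls if c.genotype == "hom_ko"]
    other = [c.embryo_id for c in calls if c.genotype == "other"]
    for name, grp in (("hom_ko", hom), ("other", other)):
        if len(grp) < 2:
            raise ValueError(f"genotype group {name!r} has {len(grp)} embryos; need >= 2")
    rows = []
    for gid in gene_ids:
        if gid not in expr.values.index:
            raise KeyError(f"gene {gid!r} absent from the expression table")
        x = expr.values.loc[gid, hom].to_numpy(dtype=float)
        y = expr.values.loc[gid, other].to_numpy(dtype=float)
        ratio = float(np.log2((x.mean() + pseudocount) / (y.mean() + pseudocount)))
        _, p = welch_t_test(x, y)
        rows.append({"gene_id": gid, "log2_ratio": ratio, "p": p})
    return pd.DataFrame(rows).set_index("gene_id")


def ko_scnt_ratio_correlation(
    ko_ratios: pd.Series | np.ndarray, scnt_ratios: pd.Series | np.ndarray
) -> CorrelationResult:
    """Spearman correlation of per-gene KO fold changes with SCNT fold changes.

    The least-squares line in the result is a tentative display aid, not a
    fitted statistical model.
    """
    ko = np.asarray(ko_ratios, dtype=float)
    sc = np.asarray(scnt_ratios, dtype=float)
    if ko.shape != sc.shape:
        raise ValueError("gene lists must be matched")
    return spearman(sc, ko)


def mendelian_chisq(obs: GenotypeCounts) -> tuple[float, int, float]:
    """Pearson chi-square of (wt, het, hom) counts against 1:2:1, df = 2."""
    if obs.total <= 0:
        raise ValueError("need at least one genotyped individual")
    observed = np.array([obs.n_wt, obs.n_het, obs.n_hom], dtype=float)
    expected = obs.total * np.array([0.25, 0.5, 0.25])
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), 2, float(p)
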