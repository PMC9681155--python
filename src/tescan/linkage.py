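"""TSS-distance linkage of TE loci to nearby genes and ratio correlation.

A gene is linked to a locus when its TSS lies 5-50 kb (``kb5_50``) or
50-200 kb (``kb50_200``) from the nearest locus boundary, on either
genomic side (TE strand ignored). Both the locus and the gene carry their
SCNT/IVF log2 expression ratio, and the association is quantified by the
Spearman correlation of those ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, SampleSheet, TELocus
from .quantify import PSEUDOCOUNT, ExpressionTable

WINDOW_NEAR = (5_000, 50_000)  # closed bounds
WINDOW_FAR = (50_000, 200_000)  # (50 kb, 200 kb]; the 50-kb boundary is near


@dataclass(frozen=True)
class LinkagePair:
    locus_id: str
    gene_id: str
    distance: int
    window: str  # "kb5_50" | "kb50_200"
    te_log2_ratio: float = np.nan
    gene_log2_ratio: float = np.nan


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    slope: float  # least-squares line, display only
    intercept: float


def tss_distance(locus: TELocus, tss: int) -> int:
    """bp from a TSS to the nearest locus boundary; 0 inside the locus."""
    if locus.start <= tss < locus.end:
        return 0
    return min(abs(tss - locus.start), abs(tss - locus.end))


def window_of(distance: int) -> str | None:
    if WINDOW_NEAR[0] <= distance <= WINDOW_NEAR[1]:
        return "kb5_50"
    if WINDOW_FAR[0] < distance <= WINDOW_FAR[1]:
        return "kb50_200"
    return None


def link_nearby_genes(loci: list[TELocus], genes: list[GeneModel]) -> list[LinkagePair]:
    """All (locus, gene) pairs whose TSS distance falls in a linkage window.

    A gene may pair with several loci and vice versa; distances below 5 kb
    (including TSS inside the locus) or above 200 kb yield no pair.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[LinkagePair] = []
    for lc in loci:
        for g in by_chrom.get(lc.chrom, []):
            d = tss_distance(lc, g.tss)
            w = window_of(d)
            if w is not None:
                pairs.append(LinkagePair(lc.locus_id, g.gene_id, d, w))
    return pairs


def condition_log2_ratio(
    expr: ExpressionTable,
    sheet: SampleSheet,
    feature_id: str,
    numerator: str = "SCNT",
    denominator: str = "IVF",
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """log2((mean_SCNT + 0.5) / (mean_IVF + 0.5)) of one feature on TPM."""
    if feature_id not in expr.values.index:
        raise KeyError(f"unknown feature {feature_id!r}")
    row = expr.values.loc[feature_id]
    num = row[sheet.samples_in(numerator)].mean()
    den = row[sheet.samples_in(denominator)].mean()
    return float(np.log2((num + pseudocount) / (den + pseudocount)))


def spearman(x: np.ndarray | list, y: np.ndarray | list) -> CorrelationResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (ties averaged); the
    p-value uses t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df, with p = 0 at
    |rho| = 1. A constant input vector makes rho undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rho undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) > 1 - 1e-14:  # snap exact monotone orderings to +/-1
        rho = 1.0 if rho > 0 else -1.0
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(rho=rho, p=p, n=n, slope=float(slope), intercept=float(intercept))


def attach_ratios(
    pairs: list[LinkagePair],
    te_expr: ExpressionTable,
    gene_expr: ExpressionTable,
    sheet: SampleSheet,
    numerator: str = "SCNT",
    denominator: str = "IVF",
) -> list[LinkagePair]:
    """Return pairs with both condition log2 ratios filled in."""
    te_cache: dict[str, float] = {}
    gene_cache: dict[str, float] = {}
    out = []
    for p in pairs:
        if p.locus_id not in te_cache:
            te_cache[p.locus_id] = condition_log2_ratio(
                te_expr, sheet, p.locus_id, numerator, denominator
            )
        if p.gene_id not in gene_cache:
            gene_cache[p.gene_id] = condition_log2_ratio(
                gene_expr, sheet, p.gene_id, numerator, denominator
            )
        out.append(
            LinkagePair(
                p.locus_id,
                p.gene_id,
                p.distance,
                p.window,
                te_cache[p.locus_id],
                gene_cache[p.gene_id],
            )
        )
    return out


def ratio_correlation(pairs: list[LinkagePair], window: str | None = None) -> CorrelationResult:
    """Spearman correlation of TE vs gene log2 ratios over pairs, optionally
    restricted to one distance window (both per-window and pooled views are
    meaningful)."""
    sel = [p for p in pairs if window is None or p.window == window]
    x = [p.te_log2_ratio for p in sel]
    y = [p.gene_log2_ratio for p in sel]
    return spearman(x, y)


def linkage_summary(pairs: list[LinkagePair], subset_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Distinct linked genes per (TE subset, window).

    ``subset_of`` maps locus_id -> subset label (e.g. subfamily); omitted,
    all loci form a single "all" subset. A gene reachable through both
    windows (via different loci) counts once per window.
    """
    rows: dict[tuple[str, str], set[str]] = {}
    for p in pairs:
        subset = subset_of.get(p.locus_id, None) if subset_of else "all"
        if subset is None:
            continue
        rows.setdefault((subset, p.window), set()).add(p.gene_id)
    records = [
        {"subset": s, "window": w, "n_genes": len(g)} for (s, w), g in sorted(rows.items())
    ]
    return pd.DataFrame(records, columns=["subset", "window", "n_genes"])


def pairs_to_frame(pairs: list[LinkagePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.locus_id, p.gene_id, p.distance, p.window, p.te_log2_ratio, p.gene_log2_ratio)
            for p in pairs
        ],
        columns=["locus_id", "gene_id", "distance", "window", "te_log2_ratio", "gene_log2_ratio"],
    )
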