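"""ChIP/input enrichment scoring over TE loci and promoters.

The genome is tiled with 2-kb bins sliding every 1 kb (so consecutive bins
overlap by half and reads are counted roughly twice in the bin total).
Per-locus RPKM is normalised to that overlapping-bin total, applied
literally:

    RPKM = count / ((length/1000) * (bin_total/1e6))

and the enrichment score is log2((ChIP RPKM + 0.5) / (input RPKM + 0.5)).
A locus is enhancer-like when its H3K27ac score is >= 1.5 on the log2
scale (threshold configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, TELocus

BIN_WIDTH = 2000
BIN_STEP = 1000
RPKM_PSEUDOCOUNT = 0.5
ENHANCER_LOG2_CUT = 1.5

PROMOTER_UP = 2000  # bp upstream of the TSS
PROMOTER_DOWN = 500  # bp downstream


@dataclass(frozen=True)
class BinGrid:
    """Sliding 2-kb/1-kb bin tiling of one chromosome."""

    chrom: str
    length: int

    @property
    def n_bins(self) -> int:
        # one bin per step while the start is inside the chromosome
        return -(-self.length // BIN_STEP) if self.length > 0 else 0

    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * BIN_STEP

    def ends(self) -> np.ndarray:
        return np.minimum(self.starts() + BIN_WIDTH, self.length)

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.starts().tolist(), self.ends().tolist()))


def make_bins(chrom_sizes: dict[str, int]) -> dict[str, BinGrid]:
    """Build the 2-kb sliding-bin grid for each chromosome."""
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
    return {chrom: BinGrid(chrom, size) for chrom, size in chrom_sizes.items()}


def downsample_to_match(
    replicate_counts: list[np.ndarray], seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Binomially thin replicates to the smallest total, then sum (merge).

    Each replicate r is thinned at keep-probability min_total/total_r, the
    sampling analogue of down-sampling reads so that replicates contribute
    equally to the merged track. Deterministic under the seed.
    """
    if not replicate_counts:
        raise ValueError("need at least one replicate")
    arrays = [np.asarray(r, dtype=np.int64) for r in replicate_counts]
    totals = [int(a.sum()) for a in arrays]
    if any(t == 0 for t in totals):
        raise ValueError("a replicate has zero total counts; cannot match depths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    min_total = min(totals)
    merged = np.zeros_like(arrays[0])
    for arr, total in zip(arrays, totals):
        if total == min_total:
            merged += arr
        else:
            merged += rng.binomial(arr, min_total / total)
    return merged


def te_rpkm(te_count: float, te_length: int, bin_total: float) -> float:
    """Per-locus RPKM normalised to the overlapping 2-kb-bin read total.

    The bin total double-counts reads (bins overlap by half); the formula
    is applied literally so scores stay comparable across marks.
    """
    if te_length <= 0:
        raise ValueError("te_length must be positive")
    if bin_total <= 0:
        raise ValueError("bin_total must be positive")
    return te_count / ((te_length / 1000.0) * (bin_total / 1e6))


def log2_enrichment(chip_rpkm: float, input_rpkm: float, pseudocount: float = RPKM_PSEUDOCOUNT):
    """log2((ChIP RPKM + 0.5) / (input RPKM + 0.5)); antisymmetric in its arguments."""
    return np.log2((np.asarray(chip_rpkm) + pseudocount) / (np.asarray(input_rpkm) + pseudocount))


def score_loci(
    loci: list[TELocus],
    chip_counts: pd.Series,
    input_counts: pd.Series,
    chip_bin_total: float,
    input_bin_total: float,
    mark: str = "H3K27ac",
    stage: str = "",
    enhancer_cut: float = ENHANCER_LOG2_CUT,
) -> pd.DataFrame:
    """Build the per-locus enrichment table (RPKMs, score, enhancer flag)."""
    rows = []
    for lc in loci:
        c_rpkm = te_rpkm(float(chip_counts[lc.locus_id]), lc.length, chip_bin_total)
        i_rpkm = te_rpkm(float(input_counts[lc.locus_id]), lc.length, input_bin_total)
        rows.append((lc.locus_id, c_rpkm, i_rpkm, float(log2_enrichment(c_rpkm, i_rpkm))))
    df = pd.DataFrame(
        rows, columns=["locus_id", "chip_rpkm", "input_rpkm", "log2_enrichment"]
    ).set_index("locus_id")
    df["mark"] = mark
    df["stage"] = stage
    df["enhancer_like"] = classify_enhancer_like(df["log2_enrichment"], mark=mark, cut=enhancer_cut)
    return df


def classify_enhancer_like(
    score: pd.Series | np.ndarray, mark: str = "H3K27ac", cut: float = ENHANCER_LOG2_CUT
) -> np.ndarray:
    """Enhancer-like iff the H3K27ac log2 enrichment is >= cut (inclusive).

    For marks other than H3K27ac the flag is always False: the definition
    is tied to the active-enhancer mark.
    """
    score = np.asarray(score, dtype=float)
    if mark != "H3K27ac":
        return np.zeros(score.shape, dtype=bool)
    return score >= cut


def promoter_interval(gene: GeneModel, chrom_length: int | None = None) -> tuple[int, int]:
    """Strand-aware promoter window: [tss-2000, tss+500) on +, mirrored on -.

    Off-chromosome ends are clipped.
    """
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_UP, gene.tss + PROMOTER_DOWN
    else:
        start, end = gene.tss - PROMOTER_DOWN, gene.tss + PROMOTER_UP
    clipped_start = max(start, 0)
    clipped_end = min(end, chrom_length) if chrom_length is not None else end
    return clipped_start, clipped_end


def _max_overlap_bin(grid: BinGrid, start: int, end: int) -> int:
    """Index of the 2-kb bin with maximal overlap; ties go to the leftmost."""
    starts = grid.starts()
    ends = grid.ends()
    overlap = np.minimum(ends, end) - np.maximum(starts, start)
    overlap = np.maximum(overlap, 0)
    return int(np.argmax(overlap))  # argmax takes the first (leftmost) maximum


def promoter_enrichment(
    genes: list[GeneModel],
    grids: dict[str, BinGrid],
    chip_bin_counts: dict[str, np.ndarray],
    input_bin_counts: dict[str, np.ndarray],
    chip_bin_total: float,
    input_bin_total: float,
) -> pd.DataFrame:
    """Per-gene promoter enrichment from the single max-overlap 2-kb bin.

    The selected bin supplies the ChIP and input counts; RPKM uses the
    nominal 2-kb bin length and the same bin totals as the locus scorer.
    """
    import warnings

    rows = []
    for gene in genes:
        grid = grids[gene.chrom]
        start, end = promoter_interval(gene, grid.length)
        if end - start < PROMOTER_UP + PROMOTER_DOWN:
            warnings.warn(
                f"promoter of {gene.gene_id} clipped to [{start},{end})", stacklevel=2
            )
        k = _max_overlap_bin(grid, start, end)
        c_rpkm = te_rpkm(float(chip_bin_counts[gene.chrom][k]), BIN_WIDTH, chip_bin_total)
        i_rpkm = te_rpkm(float(input_bin_counts[gene.chrom][k]), BIN_WIDTH, input_bin_total)
        rows.append(
            (gene.gene_id, k, c_rpkm, i_rpkm, float(log2_enrichment(c_rpkm, i_rpkm)))
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "bin_index", "chip_rpkm", "input_rpkm", "log2_enrichment"]
    ).set_index("gene_id")


def overlap_fisher(
    a: set[str], b: set[str], universe: set[str]
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of the overlap of two feature sets.

    Returns (odds ratio, p). The odds ratio is the sample cross-product
    ratio with a Haldane correction (+0.5 to every cell) when any cell is
    zero.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not (a <= universe and b <= universe):
        raise ValueError("a and b must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)
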