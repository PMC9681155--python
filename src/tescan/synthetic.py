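"""Synthetic annotation, RNA-seq and ChIP data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* TE loci placed uniformly without overlap on a small genome, labelled
  with RepeatMasker-style subfamily/family names;
* per-embryo RNA-seq counts drawn negative-binomially around log-normal
  baselines with log-normal library-size factors, with a condition-
  specific repression fold planted on a subset of one designated ERVK
  subfamily (SCNT-low loci by construction);
* genes whose SCNT/IVF fold change follows their planted linked locus
  through a multiplicative transfer slope, the TSS placed within the
  linkage window of the locus;
* Poisson ChIP/input counts over the 2-kb sliding-bin grid and over loci,
  two replicates each, with a fold enrichment planted at "enhancer" loci.

Everything is deterministic under (config, seed); stage-specific
sub-streams are derived from the single seed so each stage can be re-run
independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import CountMatrix, GeneModel, SampleSheet, TELocus
from .enrichment import BIN_STEP, BIN_WIDTH, BinGrid, make_bins

# subfamily -> (family, class); RepeatMasker-style names
SUBFAMILY_META = {
    "RLTR45-int": ("ERVK", "LTR"),
    "MMETn-int": ("ERVK", "LTR"),
    "IAPEz-int": ("ERVK", "LTR"),
    "RLTR10-int": ("ERV1", "LTR"),
    "L1Md_T": ("L1", "LINE"),
    "B1_Mus1": ("Alu", "SINE"),
    "MTA_Mm-int": ("ERVL-MaLR", "LTR"),
}

DEFAULT_PROPORTIONS = {
    "RLTR45-int": 0.12,
    "MMETn-int": 0.08,
    "IAPEz-int": 0.10,
    "RLTR10-int": 0.10,
    "L1Md_T": 0.25,
    "B1_Mus1": 0.20,
    "MTA_Mm-int": 0.15,
}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the single-embryo morula design: 12 embryos per
    condition, overdispersed counts (NB dispersion 0.05), a 4-fold
    repression (fold 0.25) planted on part of the RLTR45-int subfamily,
    an 8-fold H3K27ac ChIP enrichment at planted enhancer loci, and a
    transfer slope of 0.8 from TE to linked-gene log2 fold change.
    """

    n_chrom: int = 4
    chrom_length: int = 25_000_000
    n_te: int = 2_000
    subfamily_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_genes: int = 600
    n_embryos_per_condition: int = 12
    library_size_mean: float = 100_000.0  # expected TE reads per embryo
    baseline_log_mean: float = 3.0  # natural-log scale of baseline weights
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    repressed_subfamily: str = "RLTR45-int"
    frac_repressed: float = 0.5  # of the designated subfamily
    repression_fold: float = 0.25  # central SCNT/IVF fold of repressed loci
    repression_fold_log2_sd: float = 0.5  # per-locus spread of log2 folds
    frac_enhancer: float = 0.5  # of repressed loci planted as enhancers
    chip_enrichment_fold: float = 8.0
    chip_depth_per_kb: float = 15.0  # expected input reads per kb
    linkage_slope: float = 0.8
    linkage_window: int = 200_000
    te_length_range: tuple = (500, 5_000)
    library_factor_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subfamily_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"subfamily proportions sum to {total}, not 1")
        if self.repression_fold <= 0 or self.chip_enrichment_fold < 1:
            raise ValueError("folds must be positive (ChIP fold >= 1)")
        for name, val in (
            ("n_chrom", self.n_chrom),
            ("n_te", self.n_te),
            ("n_genes", self.n_genes),
            ("n_embryos_per_condition", self.n_embryos_per_condition),
        ):
            if val < 1:
                raise ValueError(f"{name} must be >= 1")

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator derived from the single seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])


@dataclass
class GroundTruth:
    """Planted truth: which loci are repressed/enhancer, which genes follow them."""

    repressed_locus_ids: set
    enhancer_locus_ids: set
    linked_pairs: list  # (locus_id, gene_id, slope)
    te_fold: dict  # locus_id -> SCNT/IVF fold on the mean
    gene_fold: dict  # gene_id -> SCNT/IVF fold on the mean


def _place_non_overlapping(
    rng: np.random.Generator, chrom_length: int, lengths: np.ndarray
) -> np.ndarray:
    """Uniform non-overlapping starts for intervals of the given lengths."""
    total = int(lengths.sum())
    free = chrom_length - total
    if free < 0:
        raise ValueError(
            f"cannot place {len(lengths)} loci of total {total} bp on a "
            f"{chrom_length} bp chromosome; increase chrom_length"
        )
    gaps = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    order = rng.permutation(len(lengths))
    starts = np.empty(len(lengths), dtype=np.int64)
    cum = 0
    for slot, idx in enumerate(order):
        starts[idx] = gaps[slot] + cum
        cum += lengths[idx]
    return starts


def simulate_annotation(config: SimConfig) -> tuple[list[TELocus], list[GeneModel], GroundTruth]:
    """Generate the TE annotation, gene models and planted ground truth.

    Repressed loci are a random fraction of the designated subfamily; a
    random subset of those are additionally planted as enhancers. Every
    repressed locus gets one linked gene whose TSS lies 5 kb to
    ``linkage_window`` bp from the locus boundary; remaining genes are
    placed uniformly.
    """
    rng = config.rng("annotation")
    names = list(config.subfamily_proportions)
    probs = np.array([config.subfamily_proportions[n] for n in names])
    subfam_idx = rng.choice(len(names), size=config.n_te, p=probs)
    lengths = rng.integers(
        config.te_length_range[0], config.te_length_range[1] + 1, size=config.n_te
    )
    chrom_of = rng.integers(0, config.n_chrom, size=config.n_te)

    loci: list[TELocus] = []
    per_chrom: dict[int, list[int]] = {c: [] for c in range(config.n_chrom)}
    for i, c in enumerate(chrom_of):
        per_chrom[c].append(i)
    locus_records: dict[int, tuple[str, int, int]] = {}
    for c, members in per_chrom.items():
        if not members:
            continue
        member_lengths = lengths[members]
        starts = _place_non_overlapping(rng, config.chrom_length, member_lengths)
        for idx, start in zip(members, starts):
            locus_records[idx] = (f"chr{c + 1}", int(start), int(start + lengths[idx]))
    for i in range(config.n_te):
        chrom, start, end = locus_records[i]
        sub = names[subfam_idx[i]]
        fam, cls = SUBFAMILY_META.get(sub, ("Unknown", "Unknown"))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(TELocus(f"te{i:05d}", chrom, start, end, strand, sub, fam, cls))

    designated = [lc for lc in loci if lc.subfamily == config.repressed_subfamily]
    n_rep = int(round(config.frac_repressed * len(designated)))
    rep_idx = rng.choice(len(designated), size=n_rep, replace=False) if n_rep else []
    repressed = [designated[i].locus_id for i in sorted(rep_idx)]
    n_enh = int(round(config.frac_enhancer * len(repressed)))
    enh_idx = rng.choice(len(repressed), size=n_enh, replace=False) if n_enh else []
    enhancers = [repressed[i] for i in sorted(enh_idx)]

    # per-locus repression folds spread log-normally around the central fold,
    # so repressed loci span a range of fold changes as real SCNT-low loci do
    te_fold = {lc.locus_id: 1.0 for lc in loci}
    for lid in repressed:
        log2_fold = np.log2(config.repression_fold) + config.repression_fold_log2_sd * rng.standard_normal()
        te_fold[lid] = float(2.0**log2_fold)

    # linked genes: one per repressed locus, TSS 5 kb..linkage_window away
    by_id = {lc.locus_id: lc for lc in loci}
    genes: list[GeneModel] = []
    linked_pairs: list[tuple[str, str, float]] = []
    gene_fold: dict[str, float] = {}
    gene_counter = 0
    max_d = min(config.linkage_window, 200_000)
    for lid in repressed:
        lc = by_id[lid]
        for _attempt in range(50):
            d = int(rng.integers(5_000, max_d + 1))
            side = rng.random() < 0.5
            tss = lc.end + d if side else lc.start - d
            if 0 <= tss < config.chrom_length:
                break
        else:
            raise RuntimeError("could not place a linked gene; increase chrom_length")
        gid = f"gene{gene_counter:05d}"
        gene_counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(1_000, 10_001))
        if strand == "+":
            gene = GeneModel(gid, lc.chrom, tss, "+", tss, min(tss + body, config.chrom_length))
        else:
            gene = GeneModel(gid, lc.chrom, tss, "-", max(tss + 1 - body, 0), tss + 1)
        genes.append(gene)
        linked_pairs.append((lid, gid, config.linkage_slope))
        gene_fold[gid] = 2.0 ** (config.linkage_slope * np.log2(te_fold[lid]))

    n_background = max(config.n_genes - len(genes), 0)
    for _ in range(n_background):
        gid = f"gene{gene_counter:05d}"
        gene_counter += 1
        chrom = f"chr{int(rng.integers(0, config.n_chrom)) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(1_000, 10_001))
        tss = int(rng.integers(0, config.chrom_length))
        if strand == "+":
            gene = GeneModel(gid, chrom, tss, "+", tss, min(tss + body, config.chrom_length))
            if gene.gene_end <= gene.tss:  # TSS at the very end of the chromosome
                gene = GeneModel(gid, chrom, tss - 1, "+", tss - 1, tss)
        else:
            gene = GeneModel(gid, chrom, tss, "-", max(tss + 1 - body, 0), tss + 1)
        genes.append(gene)
        gene_fold.setdefault(gid, 1.0)

    truth = GroundTruth(
        repressed_locus_ids=set(repressed),
        enhancer_locus_ids=set(enhancers),
        linked_pairs=linked_pairs,
        te_fold=te_fold,
        gene_fold=gene_fold,
    )
    return loci, genes, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _baselines(
    rng: np.random.Generator, n: int, config: SimConfig, total: float
) -> np.ndarray:
    w = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    return total * w / w.sum()


def simulate_rnaseq(
    truth: GroundTruth,
    config: SimConfig,
    loci: list[TELocus],
    genes: list[GeneModel],
) -> tuple[CountMatrix, CountMatrix, SampleSheet]:
    """Per-embryo NB counts for TE loci and genes under IVF/SCNT conditions.

    The SCNT mean of a repressed locus is its IVF mean times the
    repression fold; a linked gene's SCNT mean follows its locus through
    fold^slope. Library-size factors are log-normal with geometric mean 1.
    """
    rng = config.rng("rnaseq")
    n = config.n_embryos_per_condition
    sample_ids = [f"IVF_{i + 1:02d}" for i in range(n)] + [f"SCNT_{i + 1:02d}" for i in range(n)]
    conditions = ["IVF"] * n + ["SCNT"] * n
    lib = rng.lognormal(0.0, config.library_factor_log_sd, size=2 * n)
    lib /= np.exp(np.mean(np.log(lib)))

    te_ids = [lc.locus_id for lc in loci]
    gene_ids = [g.gene_id for g in genes]
    te_base = _baselines(rng, len(te_ids), config, config.library_size_mean)
    gene_base = _baselines(rng, len(gene_ids), config, config.library_size_mean)
    te_folds = np.array([truth.te_fold[i] for i in te_ids])
    gene_folds = np.array([truth.gene_fold[g] for g in gene_ids])

    def draw(base: np.ndarray, folds: np.ndarray) -> np.ndarray:
        out = np.empty((len(base), 2 * n), dtype=np.int64)
        for s in range(2 * n):
            fold = folds if conditions[s] == "SCNT" else np.ones_like(folds)
            out[:, s] = _nb_draw(rng, base * lib[s] * fold, config.nb_dispersion)
        return out

    te_counts = CountMatrix(
        pd.DataFrame(draw(te_base, te_folds), index=te_ids, columns=sample_ids),
        pd.Series([lc.length for lc in loci], index=te_ids),
    )
    gene_lengths = pd.Series([g.gene_end - g.gene_start for g in genes], index=gene_ids)
    gene_counts = CountMatrix(
        pd.DataFrame(draw(gene_base, gene_folds), index=gene_ids, columns=sample_ids),
        gene_lengths,
    )
    sheet = SampleSheet(pd.DataFrame({"sample_id": sample_ids, "condition": conditions}))
    return te_counts, gene_counts, sheet


@dataclass
class ChIPSim:
    """Two-replicate Poisson ChIP and input counts over bins and loci."""

    bin_chip: dict  # chrom -> (2, n_bins) arrays
    bin_input: dict
    locus_chip: pd.DataFrame  # index locus_id, columns rep1/rep2
    locus_input: pd.DataFrame


def simulate_chip(
    truth: GroundTruth,
    config: SimConfig,
    grids: dict[str, BinGrid] | None = None,
    loci: list[TELocus] | None = None,
) -> ChIPSim:
    """Poisson ChIP/input counts: length-proportional input rate, ChIP rate
    multiplied by the enrichment fold at planted enhancer loci (and the
    bins overlapping them). Replicate depths differ so that the
    depth-matching step has work to do."""
    if loci is None:
        raise ValueError("loci are required to place planted enrichment")
    if grids is None:
        grids = make_bins(config.chrom_sizes())
    rng = config.rng("chip")
    depth = config.chip_depth_per_kb
    rep_scale = np.array([1.0, float(rng.uniform(0.55, 0.85))])

    enh = truth.enhancer_locus_ids
    bin_chip: dict[str, np.ndarray] = {}
    bin_input: dict[str, np.ndarray] = {}
    for chrom, grid in grids.items():
        widths = (grid.ends() - grid.starts()).astype(float)
        base_rate = depth * widths / 1000.0
        chip_rate = base_rate.copy()
        for lc in loci:
            if lc.chrom != chrom or lc.locus_id not in enh:
                continue
            k_lo = max((lc.start - BIN_WIDTH) // BIN_STEP + 1, 0)
            k_hi = min(lc.end // BIN_STEP, grid.n_bins - 1)
            if k_hi >= k_lo:
                chip_rate[k_lo : k_hi + 1] = base_rate[k_lo : k_hi + 1] * config.chip_enrichment_fold
        bin_input[chrom] = np.stack([rng.poisson(base_rate * s) for s in rep_scale])
        bin_chip[chrom] = np.stack([rng.poisson(chip_rate * s) for s in rep_scale])

    te_ids = [lc.locus_id for lc in loci]
    lens_kb = np.array([lc.length for lc in loci]) / 1000.0
    folds = np.array([config.chip_enrichment_fold if i in enh else 1.0 for i in te_ids])
    locus_input = pd.DataFrame(
        {f"rep{r + 1}": rng.poisson(depth * lens_kb * s) for r, s in enumerate(rep_scale)},
        index=te_ids,
    )
    locus_chip = pd.DataFrame(
        {f"rep{r + 1}": rng.poisson(depth * lens_kb * folds * s) for r, s in enumerate(rep_scale)},
        index=te_ids,
    )
    return ChIPSim(bin_chip, bin_input, locus_chip, locus_input)


def write_truth(truth: GroundTruth, path) -> None:
    """Persist the planted truth as a TSV (one feature per row)."""
    rows = []
    for lid, fold in sorted(truth.te_fold.items()):
        rows.append(
            {
                "feature_id": lid,
                "kind": "te",
                "true_fold": fold,
                "repressed": lid in truth.repressed_locus_ids,
                "enhancer": lid in truth.enhancer_locus_ids,
                "linked_to": "",
            }
        )
    linked_locus = {g: l for l, g, _ in truth.linked_pairs}
    for gid, fold in sorted(truth.gene_fold.items()):
        rows.append(
            {
                "feature_id": gid,
                "kind": "gene",
                "true_fold": fold,
                "repressed": False,
                "enhancer": False,
                "linked_to": linked_locus.get(gid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_ko_experiment(
    truth: GroundTruth,
    config: SimConfig,
    loci: list[TELocus],
    genes: list[GeneModel],
    target_locus_ids: tuple[str, str],
    n_hom: int = 5,
    n_other: int = 5,
) -> tuple[CountMatrix, CountMatrix, list[str], dict[str, str]]:
    """Counts for a knockout experiment deleting two enhancer loci.

    Homozygous-knockout embryos lose expression of the targeted loci
    (means driven to ~zero, so their TPM falls below the genotyping cut)
    and their linked genes drop by 2^(-slope * planted TE log-activity),
    where the log-activity is -log2(repression_fold). Other (+/+, +/-)
    embryos keep wild-type means. Targeted loci are given a high baseline:
    loci picked for deletion are well-expressed by design.
    """
    rng = config.rng("ko")
    te_ids = [lc.locus_id for lc in loci]
    gene_ids = [g.gene_id for g in genes]
    for t in target_locus_ids:
        if t not in te_ids:
            raise KeyError(f"target locus {t!r} not in the annotation")
    te_base = _baselines(rng, len(te_ids), config, config.library_size_mean)
    gene_base = _baselines(rng, len(gene_ids), config, config.library_size_mean)
    te_base = pd.Series(te_base, index=te_ids)
    gene_base = pd.Series(gene_base, index=gene_ids)
    te_base.loc[list(target_locus_ids)] = config.library_size_mean * 0.005

    activity = -np.log2(config.repression_fold)
    ko_gene_fold = 2.0 ** (-config.linkage_slope * activity)
    linked_to_targets = [
        g for (l, g, _s) in truth.linked_pairs if l in set(target_locus_ids)
    ]

    embryos = [f"KO_{i + 1:02d}" for i in range(n_hom + n_other)]
    genotype = {e: ("hom_ko" if i < n_hom else "other") for i, e in enumerate(embryos)}
    lib = rng.lognormal(0.0, config.library_factor_log_sd, size=len(embryos))
    lib /= np.exp(np.mean(np.log(lib)))

    te_out = np.empty((len(te_ids), len(embryos)), dtype=np.int64)
    gene_out = np.empty((len(gene_ids), len(embryos)), dtype=np.int64)
    for s, emb in enumerate(embryos):
        te_mean = te_base.to_numpy().copy()
        gene_mean = gene_base.to_numpy().copy()
        if genotype[emb] == "hom_ko":
            # both alleles deleted: the locus cannot produce reads
            te_mean[[te_ids.index(t) for t in target_locus_ids]] = 0.0
            for gid in linked_to_targets:
                gene_mean[gene_ids.index(gid)] *= ko_gene_fold
        te_out[:, s] = _nb_draw(rng, te_mean * lib[s], config.nb_dispersion)
        gene_out[:, s] = _nb_draw(rng, gene_mean * lib[s], config.nb_dispersion)

    te_cm = CountMatrix(
        pd.DataFrame(te_out, index=te_ids, columns=embryos),
        pd.Series([lc.length for lc in loci], index=te_ids),
    )
    gene_cm = CountMatrix(
        pd.DataFrame(gene_out, index=gene_ids, columns=embryos),
        pd.Series([g.gene_end - g.gene_start for g in genes], index=gene_ids),
    )
    return te_cm, gene_cm, embryos, genotype
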