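"""End-to-end orchestration: simulate or load, then quantify, test,
score enrichment, link genes and (optionally) analyse a knockout.

The pipeline is driven by a single :class:`RunConfig`; one seed governs
every stochastic stage through stage-name-derived sub-streams, so a run
is reproducible from the config alone. Outputs are plain TSVs plus a
machine-readable ``report.json`` whose percentages are reported both as
raw fractions and as integers rounded half away from zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .annotation_io import (
    CountMatrix,
    SampleSheet,
    filter_autosomes,
    read_count_matrix,
    read_gene_table,
    read_sample_sheet,
    read_te_annotation,
    write_gene_table,
    write_sample_sheet,
    write_te_annotation,
)
from .differential import (
    KLASS_HIGH,
    KLASS_LOW,
    TEDifferentialModel,
    composition_summary,
    percent_of,
)
from .enrichment import downsample_to_match, make_bins, overlap_fisher, score_loci
from .ko_analysis import (
    GenotypeCounts,
    call_homozygous_ko,
    compare_adjacent_genes,
    ko_scnt_ratio_correlation,
    mendelian_chisq,
)
from .linkage import attach_ratios, link_nearby_genes, pairs_to_frame, ratio_correlation
from .quantify import compute_tpm, filter_expressed, rle_size_factors
from .synthetic import (
    SimConfig,
    simulate_annotation,
    simulate_chip,
    simulate_ko_experiment,
    simulate_rnaseq,
    write_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run.

    Either ``sim`` (synthetic mode) or the input paths (load mode) must be
    set. Thresholds default to the classification rules used throughout:
    |log2FC| >= 1 with BH-adjusted p < 0.1 for differential loci, log2
    ChIP/input >= 1.5 for enhancer-like, mean count >= 1 per embryo for
    expressed, TPM < 5 for a knockout allele, pseudocount 0.5.
    """

    out_dir: str | Path = "tescan_out"
    sim: SimConfig | None = None
    te_counts_path: str | None = None
    gene_counts_path: str | None = None
    sample_sheet_path: str | None = None
    te_annotation_path: str | None = None
    gene_table_path: str | None = None
    chip_counts_path: str | None = None  # locus_id, chip_count, input_count TSV
    chip_totals_path: str | None = None  # JSON with chip/input bin totals
    log2fc_cut: float = 1.0
    padj_cut: float = 0.1
    enhancer_cut: float = 1.5
    expressed_mean: float = 1.0
    ko_tpm_cut: float = 5.0
    pseudocount: float = 0.5
    windows: tuple = ((5_000, 50_000), (50_000, 200_000))
    run_ko: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("log2fc_cut", "padj_cut", "enhancer_cut", "expressed_mean", "ko_tpm_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        (a0, a1), (b0, b1) = self.windows
        if not (a0 < a1 == b0 < b1):
            raise ValueError("distance windows must be ordered and share only the 50-kb boundary")
        if self.sim is not None:
            self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        sim = SimConfig(**sim_raw) if sim_raw is not None else None
        if "windows" in raw:
            raw["windows"] = tuple(tuple(w) for w in raw["windows"])
        return cls(sim=sim, **raw)


def _corr_entry(pairs, window):
    try:
        r = ratio_correlation(pairs, window=window)
    except ValueError:
        return {"rho": None, "p": None, "n": len([p for p in pairs if window in (None, p.window)])}
    return {"rho": round(r.rho, 10), "p": round(r.p, 10), "n": r.n}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("tescan %s, seed %d", __version__, cfg.seed)

    try:
        report: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "thresholds": {
                "log2fc_cut": cfg.log2fc_cut,
                "padj_cut": cfg.padj_cut,
                "enhancer_cut": cfg.enhancer_cut,
                "expressed_mean": cfg.expressed_mean,
                "ko_tpm_cut": cfg.ko_tpm_cut,
                "pseudocount": cfg.pseudocount,
                "windows": [list(w) for w in cfg.windows],
            },
        }

        # ---- stage: inputs -------------------------------------------------
        truth = None
        chip_sim = None
        if cfg.sim is not None:
            logger.info("stage inputs: simulating (n_te=%d)", cfg.sim.n_te)
            loci, genes, truth = simulate_annotation(cfg.sim)
            te_counts, gene_counts, sheet = simulate_rnaseq(truth, cfg.sim, loci, genes)
            chip_sim = simulate_chip(truth, cfg.sim, loci=loci)
            write_te_annotation(loci, out / "te_annotation.bed")
            write_gene_table(genes, out / "genes.tsv")
            te_counts.write(out / "te_counts.tsv")
            gene_counts.write(out / "gene_counts.tsv")
            write_sample_sheet(sheet, out / "sample_sheet.tsv")
            write_truth(truth, out / "truth.tsv")
        else:
            logger.info("stage inputs: loading from TSVs")
            loci = read_te_annotation(cfg.te_annotation_path)
            genes = read_gene_table(cfg.gene_table_path)
            te_counts = read_count_matrix(cfg.te_counts_path)
            gene_counts = read_count_matrix(cfg.gene_counts_path)
            sheet = read_sample_sheet(cfg.sample_sheet_path)

        loci = filter_autosomes(loci)
        genes = filter_autosomes(genes)
        kept_te = [lc.locus_id for lc in loci]
        te_counts = te_counts.subset_features([i for i in te_counts.feature_ids if i in set(kept_te)])
        kept_g = {g.gene_id for g in genes}
        gene_counts = gene_counts.subset_features(
            [i for i in gene_counts.feature_ids if i in kept_g]
        )

        # ---- stage: quantify ----------------------------------------------
        logger.info("stage quantify")
        factors = rle_size_factors(te_counts)
        te_tpm = compute_tpm(te_counts)
        gene_tpm = compute_tpm(gene_counts)

        # ---- stage: differential -------------------------------------------
        logger.info("stage differential")
        model = TEDifferentialModel(
            te_counts,
            sheet,
            size_factors=factors,
            pseudocount=cfg.pseudocount,
            min_mean_count=cfg.expressed_mean,
        )
        res = model.fit()
        res.table["klass"] = res.table["klass"].where(
            res.table["klass"] == "untested",
            _reclassify(res.table, cfg.log2fc_cut, cfg.padj_cut),
        )
        res.to_tsv(out / "diff.tsv")
        comp = composition_summary(res.table, loci, level="family")
        comp.to_csv(out / "composition.tsv", sep="\t", index=False)

        n_expressed = int((res.table["klass"] != "untested").sum())
        scnt_low = set(res.features_in_class(KLASS_LOW))
        scnt_high = set(res.features_in_class(KLASS_HIGH))
        fam_of = {lc.locus_id: lc.family for lc in loci}
        sub_of = {lc.locus_id: lc.subfamily for lc in loci}
        expressed_ids = set(res.table.index[res.table["klass"] != "untested"])
        ervk_expressed = {i for i in expressed_ids if fam_of.get(i) == "ERVK"}
        ervk_low = {i for i in scnt_low if fam_of.get(i) == "ERVK"}
        report["differential"] = {
            "n_loci": int(len(res.table)),
            "n_expressed": n_expressed,
            "n_scnt_low": len(scnt_low),
            "n_scnt_high": len(scnt_high),
            "ervk_of_expressed": _frac_entry(len(ervk_expressed), n_expressed),
            "ervk_of_scnt_low": _frac_entry(len(ervk_low), len(scnt_low)),
        }

        # ---- stage: enrichment ---------------------------------------------
        logger.info("stage enrichment")
        if chip_sim is not None:
            rng = cfg.sim.rng("downsample")
            bin_reps_chip = [
                np.concatenate([chip_sim.bin_chip[c][r] for c in sorted(chip_sim.bin_chip)])
                for r in range(2)
            ]
            bin_reps_input = [
                np.concatenate([chip_sim.bin_input[c][r] for c in sorted(chip_sim.bin_input)])
                for r in range(2)
            ]
            merged_bins_chip = downsample_to_match(bin_reps_chip, rng)
            merged_bins_input = downsample_to_match(bin_reps_input, rng)
            chip_locus = pd.Series(
                downsample_to_match(
                    [chip_sim.locus_chip[c].to_numpy() for c in chip_sim.locus_chip], rng
                ),
                index=chip_sim.locus_chip.index,
            )
            input_locus = pd.Series(
                downsample_to_match(
                    [chip_sim.locus_input[c].to_numpy() for c in chip_sim.locus_input], rng
                ),
                index=chip_sim.locus_input.index,
            )
            chip_bin_total = float(merged_bins_chip.sum())
            input_bin_total = float(merged_bins_input.sum())
            pd.DataFrame(
                {"chip_count": chip_locus, "input_count": input_locus}
            ).rename_axis("locus_id").to_csv(out / "chip_locus_counts.tsv", sep="\t")
            with open(out / "chip_totals.json", "w") as fh:
                json.dump(
                    {"chip_bin_total": chip_bin_total, "input_bin_total": input_bin_total},
                    fh,
                    sort_keys=True,
                )
            enr_available = True
        elif cfg.chip_counts_path is not None:
            df = pd.read_csv(cfg.chip_counts_path, sep="\t", index_col=0)
            chip_locus, input_locus = df["chip_count"], df["input_count"]
            with open(cfg.chip_totals_path) as fh:
                totals = json.load(fh)
            chip_bin_total = float(totals["chip_bin_total"])
            input_bin_total = float(totals["input_bin_total"])
            enr_available = True
        else:
            enr_available = False

        enhancer_like: set = set()
        if enr_available:
            enr = score_loci(
                loci,
                chip_locus,
                input_locus,
                chip_bin_total,
                input_bin_total,
                mark="H3K27ac",
                enhancer_cut=cfg.enhancer_cut,
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")
            enhancer_like = set(enr.index[enr["enhancer_like"]])
            odds, fisher_p = overlap_fisher(
                scnt_low & expressed_ids, enhancer_like & expressed_ids, expressed_ids
            )
            low_ervk_enh = {i for i in ervk_low if i in enhancer_like}
            low_rltr = {i for i in scnt_low if sub_of.get(i) == "RLTR45-int"}
            low_rltr_enh = low_rltr & enhancer_like
            report["enrichment"] = {
                "n_enhancer_like": len(enhancer_like),
                "fisher_scnt_low_vs_enhancer_like": {
                    "odds_ratio": round(odds, 10),
                    "p": float(f"{fisher_p:.10g}"),
                },
                "enhancer_like_of_scnt_low_ervk": _frac_entry(len(low_ervk_enh), len(ervk_low)),
                "enhancer_like_of_scnt_low_rltr45": _frac_entry(len(low_rltr_enh), len(low_rltr)),
            }

        # ---- stage: linkage -------------------------------------------------
        logger.info("stage linkage")
        subset_ids = (scnt_low & enhancer_like) if enhancer_like else scnt_low
        subset_loci = [lc for lc in loci if lc.locus_id in subset_ids]
        pairs = link_nearby_genes(subset_loci, genes)
        pairs = attach_ratios(pairs, te_tpm, gene_tpm, sheet)
        pairs_to_frame(pairs).to_csv(out / "linkage.tsv", sep="\t", index=False, float_format="%.6g")
        report["linkage"] = {
            "subset": "SCNT_low_enhancer_like" if enhancer_like else "SCNT_low",
            "n_pairs": len(pairs),
            "pooled": _corr_entry(pairs, None),
            "kb5_50": _corr_entry(pairs, "kb5_50"),
            "kb50_200": _corr_entry(pairs, "kb50_200"),
        }

        # ---- stage: knockout (synthetic mode only) ---------------------------
        if cfg.sim is not None and cfg.run_ko and truth is not None:
            targeted = _pick_ko_targets(truth)
            if targeted is not None:
                logger.info("stage ko: targets %s", targeted)
                te_ko, gene_ko, embryos, true_geno = simulate_ko_experiment(
                    truth, cfg.sim, loci, genes, targeted
                )
                combined = CountMatrix(
                    pd.concat([te_ko.counts, gene_ko.counts]),
                    pd.concat([te_ko.lengths, gene_ko.lengths]),
                )
                ko_tpm = compute_tpm(combined)
                calls = call_homozygous_ko(ko_tpm, targeted, tpm_cut=cfg.ko_tpm_cut)
                adjacent = [g for (l, g, _s) in truth.linked_pairs if l in set(targeted)]
                cmp_tbl = compare_adjacent_genes(ko_tpm, calls, adjacent, cfg.pseudocount)
                cmp_tbl.to_csv(out / "ko.tsv", sep="\t", float_format="%.6g")
                scnt_ratios = [
                    float(
                        np.log2(
                            (gene_tpm.values.loc[g, sheet.samples_in("SCNT")].mean() + cfg.pseudocount)
                            / (gene_tpm.values.loc[g, sheet.samples_in("IVF")].mean() + cfg.pseudocount)
                        )
                    )
                    for g in adjacent
                ]
                ko_corr = None
                if len(adjacent) >= 3:
                    try:
                        r = ko_scnt_ratio_correlation(
                            cmp_tbl["log2_ratio"].to_numpy(), np.array(scnt_ratios)
                        )
                        ko_corr = {"rho": round(r.rho, 10), "p": round(r.p, 10), "n": r.n}
                    except ValueError:
                        ko_corr = None
                litter = cfg.sim.rng("litter").multinomial(32, [0.25, 0.5, 0.25])
                chi2, df, chi_p = mendelian_chisq(GenotypeCounts(*map(int, litter)))
                report["ko"] = {
                    "targets": list(targeted),
                    "n_hom_ko_called": sum(c.genotype == "hom_ko" for c in calls),
                    "genotype_accuracy": float(
                        np.mean([c.genotype == true_geno[c.embryo_id] for c in calls])
                    ),
                    "n_adjacent_genes": len(adjacent),
                    "frac_adjacent_down": float(np.mean(cmp_tbl["log2_ratio"] < 0))
                    if len(adjacent)
                    else None,
                    "ko_scnt_correlation": ko_corr,
                    "mendelian": {
                        "observed": [int(x) for x in litter],
                        "chi2": round(chi2, 10),
                        "df": df,
                        "p": round(chi_p, 10),
                    },
                }

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("done")
        return report
    except Exception as exc:
        logger.exception("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _reclassify(table: pd.DataFrame, log2fc_cut: float, padj_cut: float) -> pd.Series:
    from .differential import classify_differential

    return pd.Series(
        classify_differential(table["log2fc"], table["padj"], log2fc_cut, padj_cut),
        index=table.index,
    )


def _frac_entry(n: int, total: int) -> dict:
    pct = percent_of(n, total)
    return {
        "n": int(n),
        "total": int(total),
        "fraction": (round(n / total, 10) if total else None),
        "percent": pct,
    }


def _pick_ko_targets(truth) -> tuple[str, str] | None:
    """Two planted enhancer loci that have linked genes, as deletion targets."""
    linked_loci = {l for (l, _g, _s) in truth.linked_pairs}
    candidates = sorted(truth.enhancer_locus_ids & linked_loci)
    if len(candidates) < 2:
        return None
    return candidates[0], candidates[1]
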