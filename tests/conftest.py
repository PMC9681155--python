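import pytest

from tescan.synthetic import SimConfig, simulate_annotation, simulate_rnaseq


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared across tests (seed 0)."""
    cfg = SimConfig(seed=0)
    loci, genes, truth = simulate_annotation(cfg)
    te_counts, gene_counts, sheet = simulate_rnaseq(truth, cfg, loci, genes)
    return {
        "cfg": cfg,
        "loci": loci,
        "genes": genes,
        "truth": truth,
        "te_counts": te_counts,
        "gene_counts": gene_counts,
        "sheet": sheet,
    }


@pytest.fixture()
def recovery_config():
    """5,000 loci with ~200 planted repressed RLTR45-int (4-fold)."""
    props = {
        "RLTR45-int": 0.08,
        "MMETn-int": 0.07,
        "IAPEz-int": 0.10,
        "RLTR10-int": 0.10,
        "L1Md_T": 0.25,
        "B1_Mus1": 0.20,
        "MTA_Mm-int": 0.20,
    }
    return SimConfig(
        seed=0,
        n_te=5000,
        n_chrom=8,
        subfamily_proportions=props,
        frac_repressed=0.5,
        repression_fold=0.25,
    )
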