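# Methods

## The analysis model

`tescan` treats each annotated repeat interval (a *TE locus*) as a
feature of a counts-by-samples experiment comparing two embryo
conditions (IVF vs SCNT, or knockout vs other). The pipeline's stages
and their assumptions:

### Coordinates and filtering

All intervals are 0-based half-open (BED convention), enforced at the
readers: RepeatMasker `.out` 1-based inclusive starts are converted by
`start − 1`. Sex chromosomes (`chrX`/`X`/`chrY`/`Y`, matched by name)
are removed before any group comparison because IVF embryo pools mix
sexes while SCNT embryos are clonal, so X/Y dosage is confounded with
condition. A locus is *expressed* when it averages at least one read per
embryo over all samples pooled (boundary inclusive); only expressed loci
are tested.

### Normalisation

TPM and CPM follow the standard definitions; size factors are RLE
(median-of-ratios): the per-feature reference is the geometric mean
across samples over features with no zero anywhere, per-sample factors
are the median count/reference ratio, rescaled to geometric mean 1.
All expression log-ratios use a pseudocount of 0.5 so that features
silent in one condition keep a finite ratio. The 0.5 constant is the
same one the enrichment scorer uses on RPKMs; a single constant is used
everywhere for uniformity and is configurable.

### Differential testing

Per feature, normalised counts in each group are summarised by their
mean μ̂ and variance s². The NB dispersion is estimated by method of
moments pooled within groups,

    α̂ = [Σ_g (n_g−1)(s²_g − μ̂_g)] / [Σ_g (n_g−1) μ̂_g²],  floored at 1e-8,

with no shrinkage across features — a deliberate choice favouring
transparency and testability over small-sample efficiency; the package
does not attempt numerical equivalence with shrinkage-based NB fitters,
whose contract here is only the classification rule. The Wald statistic
is log2FC/SE with the delta-method SE from Var(K/f) = μ/f + αμ²
(size factors f enter through the within-group mean of 1/f), and a
two-sided normal p-value. With 12 embryos per group the normal reference
makes the test mildly anti-conservative (empirical type-I error ≈ 0.06
at nominal 0.05 on the synthetic null) — the t-vs-normal small-sample
effect; the double threshold (|log2FC| ≥ 1 *and* BH-adjusted p < 0.1)
keeps the SCNT-low/high lists essentially free of null features.

Classification boundaries follow the printed inequalities exactly:
|log2FC| ≥ 1 inclusive, adjusted p < 0.1 exclusive. Composition
percentages are integers rounded half away from zero, matching the
style of reported fractions such as 45% for 497/1,109.

### Enrichment scoring

Chromosomes are tiled with 2-kb bins every 1 kb (the last bins truncated
at the chromosome end), so consecutive bins overlap by half and the
genome-wide bin total counts each read roughly twice. The per-locus
RPKM formula is applied literally against that overlapping-bin total —
scores are therefore about half of a conventional RPKM, but comparable
across marks and stages, which is what the classification needs.
Replicates are depth-matched before merging by binomial thinning at
keep-probability min_total/total, the sampling analogue of read-level
down-sampling. The enhancer-like threshold (1.5) is interpreted on the
log₂ scale (≈2.8-fold), because enrichment is defined as the log₂
ChIP/input ratio immediately before the threshold is stated; the
threshold and its scale are configurable, and the flag is tied to the
H3K27ac mark (other marks never classify a locus as enhancer-like).
Promoters are strand-aware windows [TSS−2000, TSS+500) (mirrored on −),
scored from the single maximally-overlapping 2-kb bin (ties to the
leftmost), with the nominal 2-kb length in the RPKM.

### Gene linkage

Distance is measured from the gene's TSS to the nearest locus boundary
(not the midpoint), on either genomic side; TE strand is ignored. The
windows are closed at 5 kb and 200 kb, with the shared 50-kb boundary
assigned to the near (5–50 kb) window — a deterministic tie rule the
stated ranges do not fix. A TSS inside a locus (distance 0) never links.
Correlations of TE and gene condition ratios are computed per window and
pooled, as Spearman rho on mid-ranks with the two-sided t-approximation
p-value (p = 0 at |rho| = 1, error on constant input). The least-squares
line carried in the result is a display aid only.

### Knockout analysis

An embryo is homozygous-knockout when *both* targeted loci are strictly
below 5 TPM. "Other" pools +/+ and +/− embryos. Adjacent genes are
compared by Welch two-tailed t-tests (Welch is used wherever a
two-tailed t-test is called for, since the equal-variance assumption is
never warranted for per-embryo expression); degenerate zero-variance
comparisons return p = 1 when the means agree and p = 0 otherwise.
Litter genotype counts are tested against 1:2:1 (het × het cross) by
Pearson chi-square with df = 2.

## The synthetic generator

The generator emulates the data structure the analysis assumes, not the
sequencing process:

* **Annotation** — `n_te` loci (default 2,000; lengths uniform
  0.5–5 kb) placed uniformly without overlap on `n_chrom` × 25-Mb
  chromosomes, with RepeatMasker-style subfamily labels in configurable
  proportions.
* **RNA counts** — gamma-Poisson (negative binomial) with
  Var = μ + αμ², α = 0.05 by default; baselines log-normal (so mean
  counts ≈ 50 with a realistic spread at the default 100k reads per
  embryo over 2,000 loci); library-size factors log-normal (sd 0.2,
  geometric mean 1) to give the RLE normaliser something to estimate;
  12 embryos per condition, the study's single-embryo design scale.
* **Planted repression** — a fraction (default half) of one designated
  subfamily (RLTR45-int) is repressed in SCNT; per-locus folds are drawn
  log-normally around the central fold (default 0.25, log₂ sd 0.5) so
  that repressed loci span a range of effect sizes, which is what makes
  a locus-vs-gene ratio correlation meaningful.
* **Linked genes** — every repressed locus gets one gene with TSS placed
  5 kb–`linkage_window` from the locus; its SCNT fold is
  `te_fold^slope` (slope 0.8 by default), entering multiplicatively on
  the mean. Background genes are placed uniformly.
* **ChIP** — Poisson counts with a length-proportional input rate
  (15 reads/kb, ≥30 expected reads at a typical locus) and the
  enrichment fold (default 8) applied to ChIP rates at planted enhancer
  loci and the bins overlapping them; two replicates at different depths
  so the depth-matching step is exercised.
* **Knockout** — homozygous embryos produce zero reads at the deleted
  loci (the DNA is gone) and their linked genes drop by
  2^(−slope · log₂-activity) with activity = −log₂(repression_fold).

What the generator does **not** emulate: mappability and multi-mapping
artifacts, GC/length biases, sequence content, developmental-stage
mixtures, or correlated fluctuations between loci. Passing tests
therefore demonstrate that the statistics recover effects of the assumed
form at realistic depth and replication — not that the pipeline is
robust to alignment artifacts in real repeat data.

Determinism: every stage draws from a generator seeded by
(seed, crc32(stage-name)), so one seed reproduces a whole run and stages
can be re-run independently.

## Numerical choices and degenerate inputs

* BH adjustment is the step-up procedure with explicit monotonicity
  enforcement; order-preserving; input p outside [0, 1] is an error.
* All-zero features get finite log2FC through the pseudocount but are
  reported `untested` (no p) when they fail the expressed filter or
  carry no information at all.
* Fisher's exact test reports the sample odds ratio with a Haldane
  +0.5 correction when any cell is zero; the p-value is the exact
  two-sided hypergeometric probability.
* Spearman rho is snapped to ±1 within 1e-14 so exact monotone inputs
  report p = 0.
* The expressed filter, classification and window assignment are pure
  functions; classification is invariant under sample reordering, and
  swapping condition labels negates log2FC and exchanges the SCNT-low
  and SCNT-high classes exactly.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 2,000 loci
× 24 embryos for calibration checks, 5,000 loci for parameter recovery,
2 × 25-Mb chromosomes for full-pipeline determinism. These sizes give
Monte-Carlo error comfortably inside the asserted bands (e.g. the
rejection-rate band at nominal α = 0.05 is ±0.02 with ~2,000 null
features) while keeping the whole suite under a minute of simulation
time.

## Known limitations

* The dispersion estimator has no shrinkage: power at very low counts is
  below that of shrinkage-based NB fitters, and the Wald-normal
  reference is mildly anti-conservative at a dozen embryos per group.
* The enrichment model is thin — locus and bin counts are drawn from
  rates, not reads, so locus scores and bin tracks are statistically
  independent in the generator.
* Real-data headline numbers (tens of thousands of expressed loci,
  specific adjusted p-values) require the original sequencing data and
  genome annotation; the package validates the method's behaviour on
  planted truth and the printed composition arithmetic instead.
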