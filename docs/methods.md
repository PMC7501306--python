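# Methods

This note documents the models, parameter choices and numerical conventions
behind `stemscreen`, and what the synthetic-data tests do and do not show
about real data.

## Screen model and hit calling

**Data model.** Each well holds per-cell γH2AX mean intensities (MI,
arbitrary units). Per-cell MI is modelled multiplicatively:

    MI = baseline × gene_effect × W × C

with `W ~ logNormal` a well-level factor (CV = `plate_cv`, default 0.05,
capturing transfection/position variability between wells) and
`C ~ logNormal` a per-cell factor (CV = `cell_cv`, default 0.30, capturing
cell-to-cell staining heterogeneity). Both factors have unit mean, so with
all CVs at zero a well's mean MI equals the baseline exactly — a property
the unit tests exploit. A log-normal noise model keeps intensities strictly
positive and makes the CV the natural noise parameter.

**Plate layout.** One well per library gene per population (GSC/DGC), plus
16 scrambled-control and 4 positive-control wells per population at the
default 296-gene scale. The default planted scenario carries three
GSC-specific hits at 1.4× (SPT6, BRCA1, WEE1 — a hit rate of ~1%, i.e. hits
are rare relative to the library). Layout counts are configuration, not
claims about any particular physical plate.

**Statistics.** Fold change is the well mean over the mean of qc-passing
scrambled wells of the same plate and population. The z-score reference is
all qc-passing *sample* wells of that plate/population (population SD,
ddof = 0): because hits are rare, sample wells approximate a null
distribution; a robust median/MAD variant is available
(`zscore(..., robust=True)`). The hit rule operates on fold change —
`fc_GSC ≥ 1.20` (inclusive) and `fc_DGC < 1.20` (strict) — with z reported
for ranking context. Wells with fewer than `min_cells = 50` cells are
excluded; the default stabilizes well means and is configurable.

**Calibration caveat.** Scrambled-well z-scores are calibrated (mean ≈ 0,
SD ≈ 1) on *null* plates. When hits are planted, the sample-well reference
SD is inflated by the hit mixture, so scrambled z-scores shrink slightly;
the validation suite therefore measures z calibration on matched no-hit
screens and hit recovery on planted screens.

## Paired count model and differential testing

**Generator.** Counts are negative-binomial with mean
`lib_size × rel_abundance × pair_baseline × 2^lfc·[condition B]` and
per-gene dispersion (default ~0.1, log-normal jitter). The pair baseline
(CV 0.10) is shared by both members of a pair, mimicking
experiment-to-experiment level shifts that a paired design absorbs;
dispersion below 1e-12 collapses to the Poisson limit. Gene lengths
(log-normal around ~1.7 kb) make RPKM computable. The default planted
scenario is 2000 genes, 3 pairs, 10% differential at log2FC ±1.5 with
balanced signs.

**Filtering and normalization.** The expression filter keeps genes strictly
above 1 RPKM in at least 3 samples, computed on raw library sizes
(filter-before-normalize; a flag switches to TMM-effective sizes). TMM
follows the published recipe: reference sample = the one whose 75th
count-fraction percentile is closest to the mean; M/A computed over genes
nonzero in both samples; 30% two-sided trim on M and 5% on A (rank-based,
intersected); inverse-delta-method-variance weighted mean of M; factors
normalized to geometric mean 1. The implementation reproduces Bioconductor
edgeR's `calcNormFactors(method="TMM")` to < 1e-6 on a frozen fixture.

**Test.** Differential expression uses a per-gene paired two-sided t-test
on within-pair `log2(CPM+1)` differences; log2FC is the mean within-pair
difference. This deliberately approximates a negative-binomial GLM with a
pairing covariate: it honours the paired design, is exactly calibrated
under permutation symmetry, and keeps the pipeline free of a GLM fitting
dependency. Externally produced DE tables (TSV with columns gene, log2fc,
mean_log2cpm, p, fdr) are accepted at every downstream step, which is the
intended route when a dedicated count-model fit is available. Degenerate
genes whose pair differences are all equal get p = 1 (difference zero) or
p = 0 (nonzero) — a convention for noise-free synthetic inputs. BH
adjustment is the step-up rule with enforced monotonicity, capped at 1.

**Power at n = 3 pairs.** With df = 2 the smallest attainable p-values are
large, so genome-wide FDR calls are underpowered at the default effect
sizes; the validation suite accordingly scores *estimation* (fold-change
recovery, Spearman ≥ 0.8 over planted genes) and *calibration* (type-I
fraction at α = 0.05 within 3·√(α(1−α)/2000) of α, pooled over 50 seeds)
rather than significance counts. Note that with binary ±1.5 planted
effects, the Spearman over planted genes has a ceiling of √3/2 ≈ 0.866
(rank correlation against a two-level truth), which clean recovery attains.

**Concordance and half-life check.** Cross-dataset concordance is the
Spearman correlation of log2FC vectors over the gene intersection, with a
trend curve (genes sorted by the x-table log2FC; sliding window of
⌈0.05·n⌉ genes stepping one gene; symmetric windows truncated at the ends;
SE = SD/√window-n) and 2D bin counts for density plotting. The half-life
bias check correlates log2FC with per-gene mRNA half-life and raises a
flag at |r_s| > 0.3 (configurable); a strong correlation would mean the
differential signal merely tracks transcript stability under a global
transcription decline.

**Signatures.** Top-n per direction ranked by raw p-value (n = 500 for
perturbation-database queries, n = 250 for the derived stem-cell set),
ties broken by |log2FC| descending then gene symbol — a deterministic
total order.

## Overrepresentation

One-sided (greater) Fisher exact test on
`[[k, n−k], [m−k, N−n−m+k]]` after intersecting set members with the
universe; the universe is the post-filter expression space by default. The
reported odds ratio is the sample odds ratio with 0/0 → NaN and x/0 → ∞.
BH runs within each direction separately. Keyword curation matches
lower-cased substrings (not word boundaries, so `non_homologous` matches
inside longer tokens); the stem-cell rule's exclusion words are matched
against set names, since plain GMT dialects do not carry reliable
description fields. GO sets are filtered to a single ontology level
(default 6) using level metadata carried in the GMT description; no DAG
traversal is performed. Gene symbols are upper-cased and de-duplicated on
ingest — inputs must share one symbol namespace.

## Enrichment map

Nodes are significantly overrepresented sets of one direction (default
FDR < 0.01; up and down are clustered separately). Edges carry the Jaccard
similarity and survive when `J ≥ 0.15` **and** overlap ≥ 5 genes (both
inclusive). Louvain runs on the Jaccard-weighted graph; because a single
greedy sweep is easily trapped in local optima on small unstructured
graphs, the sweep is restarted 16 times with visit orders derived from the
seed and the highest-modularity partition is kept — deterministic for a
fixed seed, and within the validation suite it matches the exhaustive
modularity optimum on all tested ≤ 8-node graphs. Modularity is weighted
Newman `Q = Σ_c [Σ_in/2m − (Σ_tot/2m)²]`. Community ids are relabelled
contiguously by each community's lexicographically smallest member, so
labels are stable across runs.

**Titling.** Set names are tokenized on any non-alphanumeric run
(underscores split, numerals kept), lower-cased, and stripped of a fixed
English stop-word snapshot shipped with the package plus the gene-set
noise words (reactome, kegg, dn, up, network, corr). Each cluster's token
multiset is one document: tf = count / cluster token total; idf = ln(C /
clusters containing the word), no smoothing; top 10 words per cluster,
ties by raw frequency then alphabetically. With a single cluster all idf
vanish and the title falls back to the most frequent words. Only clusters
spanning ≥ 2 collection sources are flagged annotated; single-source
clusters keep their titles but carry an NA flag. Removing unconnected
clusters is a presentation choice and is exposed only as an optional
`drop_singletons` switch.

**Planted-cluster generator.** Sets within a planted cluster draw from a
shared pool of 1.5× the maximum set size, giving expected within-cluster
Jaccard r/(2−r) ≈ 0.5 at r = size/pool = 2/3; pools are disjoint between
clusters, so between-cluster overlap is exactly zero. Set names interleave
a source word, the cluster vocabulary and a per-set filler token; sources
cycle within a cluster so every planted cluster is multi-source.

## Per-cell assays

**Generator.** Phases are drawn from a mixture (default G1 0.55, S 0.25,
G2 0.12, M 0.03, polyploid 0.05 — an asynchronous population with a modest
polyploid tail). Intensity channels are two-component log-normal mixtures
(σ = 0.3 in natural log) whose positive mode sits `channel_separation`
(default 2.0) log-units above the negative mode; EdU is positive iff S,
cyclin A iff S/G2, H3S10 iff M. DNA content is anchored at 2N for G1
(mode 2.0), uniform 2.3–3.7 for S, 4N for G2/M and ~8N for polyploid
cells. Foci counts are Poisson with per-(marker, phase, condition) rates;
the default treated arm doubles the S/G2 53BP1 rate (2 → 4), the planted
de-regulated end-joining signal. Nuclear area is log-normal with mean 100
and SD 20 (arbitrary units). Reporter channels mark a transduced (BFP+)
fraction of 0.6 with a per-condition repair (GFP+) rate.

**Gating.** Interactive manual gating is replaced by a
deterministic rule: each channel's positivity threshold is the midpoint (in
log space) of a two-component Gaussian-mixture fit (fixed random state);
when the fitted modes are closer than 0.5 log-units the channel is treated
as unimodal-negative and the threshold falls back to mean + 3 SD of the
log intensities. The polyploid cut is 2.25× the G1 DNA mode (i.e. 4.5N
with G1 at 2N; the G1 mode is the kernel-density peak restricted to ≤1.2×
the median, which presumes G1 is the dominant sub-2N-to-4N population);
both the factor and explicit thresholds are configurable. Phase precedence
polyploid > M > S > G2 > G1 resolves double-positives deterministically.

**Scores.** Foci densities are counts per nucleus divided by nuclear area
(NA), averaged with SEM per group — the density mean estimates
λ·E[1/NA], and condition ratios cancel the area distribution, which is
why the planted 2× S/G2 rate appears as a dNHEJ ratio of ≈ 2. dNHEJ is the
53BP1 density restricted to gated S/G2 cells; HR proxy = BRCA1 density in
S/G2; NHEJ proxy = 53BP1 density in G1. Population fractions are simple
percentages over gated positivity; the reporter repair rate is the GFP+
fraction among BFP+ (transduced) cells. ΔΔCT averages CT within
(condition, gene) before differencing; ChIP fold enrichment adjusts the
input CT by log2(1/fraction) and ratios percent-input values. Group
comparison is a Student t-test (equal-variance default matching the
"unpaired t-test" convention; Welch by flag).

## Randomness and determinism

One root seed drives everything; each generator stage derives an
independent child stream from a CRC32-labelled `SeedSequence`, so
regenerating one input never perturbs another. Louvain restarts and the
GMM gates use seeds derived from the stage seed or fixed states. Every CLI
stage rerun with the same inputs, seed and config produces byte-identical
files; the test suite asserts this across all stages.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the pipeline assumes:
multiplicative well noise, NB counts with a paired baseline, high
within-cluster set overlap, separable intensity mixtures, Poisson foci.
They deliberately omit plate spatial gradients, siRNA off-target effects,
guide-level variability, count-model misspecification (e.g. zero
inflation), overlapping real MSigDB vocabulary, segmentation errors and
channel bleed-through. Passing recovery tests therefore demonstrates that
the *computations* are correct and calibrated under their stated models —
not that any particular biological dataset satisfies those models. Problem
sizes in the validation suite (100 screen seeds at 296 genes × 200
cells/well, 50 null DE seeds at 2000 genes × 3 pairs, 20 enrichment-map
seeds at 4 × 8 sets, 5000 cells per assay condition) were chosen to make
Monte-Carlo error small relative to the tested tolerances while keeping a
full run in tens of seconds.

## Known limitations

- The paired t-test is not a count model; at very low counts or extreme
  dispersion its p-values drift from NB-GLM ones. Use an external DE table
  for production inference at small n.
- The screen z-score reference (sample wells) assumes a low hit rate;
  screens with dense hits should use the robust variant.
- The G1-anchored polyploid gate assumes G1 is the dominant non-polyploid
  peak; heavily arrested populations should pass explicit thresholds.
- Keyword curation is substring-based by design and will match embedded
  words (e.g. "repair" inside "misrepair").
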