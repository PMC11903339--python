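# Methods

This note documents the models and procedures implemented in
`opscreen`, the defaults they use, and the choices made where the
design was genuinely open.

## The screen model the synthetic generator emulates

A pooled optical screen delivers one row per cell: plate, guide
barcode, gene, and a few thousand CellProfiler-style morphological
features named `Object_Class_Params_Channel` (e.g.
`Cells_Granularity_1_WGA`). The generator reproduces the statistical
features of such data that the analysis depends on; it makes no attempt
to synthesize images or spatial neighborhoods.

**Cell counts.** Guide representation in real screens is strongly
overdispersed (hundreds of cells per gene on average with an s.d. of
comparable magnitude). We model a gene-shared Gamma frailty
`g ~ Gamma(k, 1/k)` with per-guide counts `Poisson(g · m)`, where `m =
cells_per_guide_mean` (default 125) and `k =
cells_per_guide_dispersion` (default 0.56). Marginally each guide is
negative-binomial NB(m, k); summed over 4 guides the gene totals have
mean 500 and s.d. ≈ 660 at the defaults, matching the coverage regime
of genome-scale screens, while keeping the fraction of guides with no
cells at a realistic few percent (an independent per-guide NB fit to
the guide-level s.d. alone would leave over a third of guides empty,
which real screens do not show). Guides that draw zero cells stay in
the library with zero rows.

**Feature values.** A cell's feature vector is
`plate offset + (gene effect if its guide is active) + noise`. Noise is
unit-variance Gaussian with equicorrelated blocks per channel
(`noise_block_corr`, default 0.3): features of one stain are correlated
in real data because they measure the same underlying signal, and this
redundancy is what feature selection must remove. Plate offsets are
N(0, `plate_effect_sd`=0.2) per plate × feature and are eliminated by
per-plate standardization. The normal-block noise family is an
assumption — the noise family of real screens is not characterized —
so distributional results here should be read as demonstrations of the
pipeline's logic, not of its behaviour under arbitrary noise.

**Planted effects.** A fraction `frac_hit_genes` (default 0.1) of genes
carry an effect vector; each affected feature is shifted by
`effect_size` cell-level noise s.d. (default 1.0, jittered ×U(0.5,1.5)),
on a sparse feature subset chosen so that `compartment_specificity`
(default 0.55) of the squared effect mass lies in the gene's home
channel. We deliberately scale effects per affected feature rather than
normalizing the whole vector: knockouts with visible phenotypes move
dozens of features by on the order of one s.d., and a unit-norm dense
vector at desk scale would put ~0.04 s.d. in every feature and make
every planted hit statistically invisible — a property of the
normalization, not of the pipeline. Genes grouped into synthetic
complexes (`frac_complexed` of hits, sizes 3–6) share a prototype
direction up to jitter; members flip sign with probability
`frac_anticorrelated` (default 0.2), emulating inhibitory complex
members whose profiles anticorrelate with activators. Guide activity is
Bernoulli(`guide_activity_prob`, default 0.9, the upper end of measured
Cas9 editing efficiencies); an inactive guide produces exactly the null
distribution. An optional flat `cutting_effect_size` adds a common
shift to *all* targeting guides, including those of unexpressed genes —
the nonspecific-cutting signal whose removal is the purpose of the
zero-TPM null.

**Granularity conservation.** Granularity measures signal removed by
successive erosions relative to total signal, so mass gained at one
size must be lost at others. Within each (object, channel) the
generator passes its granularity entries through a softmax scaled to
`granularity_total` (default 100), so every cell's spectrum sums to the
total exactly; planted effects and noise act on the logits. The planted
"V-ATPase-like" group (`n_vatpase_like`) shifts the WGA logits down at
size 1 and up at larger sizes — the signature of lysosomal
acidification loss — with no sign flips within the group, since loss of
any subunit acts in the same direction.

**Annotations.** Pairwise link scores are `round(999 · clip(|cos θ| +
ε))` over truth effect vectors (ε ~ N(0, noise_sd), default 0.05) for
within-complex pairs plus random pairs — a monotone noisy transform of
true profile similarity, like a protein-interaction confidence score.
Dependency scores for a `frac_essential` subset decrease with effect
magnitude below −0.5; expression is lognormal except for the
`frac_zero_tpm` unexpressed genes, which have TPM exactly 0 and zero
effect vectors.

## Profiling

Median aggregation per (plate, guide); standardization per plate with
the population s.d. (ddof = 0, the standard-scaler convention);
features with zero variance within a plate are flagged and set missing.
Feature selection operates per screen on the concatenated per-plate
guide profiles: features missing anywhere are dropped, features with
s.d. < 1e-8 are dropped, then pairs with |Pearson r| above 0.9 are
resolved iteratively by dropping, within the worst pair, the feature
with the larger mean absolute correlation to all others (the
established profiling-workflow convention); the procedure is idempotent
and the retained set's max pairwise |r| is verified exhaustively in
tests. Guide- and gene-level profiles are medians of the selected
per-plate and per-guide profiles respectively. PCA retains the smallest
k components whose cumulative explained-variance ratio reaches the
target (default 0.90), computed with a full SVD for determinism.

## Hit calling

Test unit: per-screen guide-level profiles — each gene's guides
(typically 4) against all nontargeting guide profiles, per feature, by
a two-sided Mann–Whitney U-test: exact null distribution when the
smaller group has ≤ 8 units and no ties, tie- and continuity-corrected
normal approximation otherwise. Genes with fewer than two guide
profiles cannot be tested and are skipped with a warning.

The profile score counts features with p < α (default 0.001); the
morphological signal score is Σ −log₁₀ pᵢ over those features (base 10;
configurable). Per-channel scores count significant features within the
channel's subset — texture, intensity, correlation, radial distribution
and granularity features of that channel, with two-channel correlation
features belonging to both their channels' subsets.

The hit threshold is the zero-TPM null score at ascending rank
⌈(1−FDR)·m⌉ with no interpolation, and hits must be **strictly**
greater; this caps the flagged-null fraction at the FDR plus at most
one order-statistic step, for any null score distribution. Each channel
is thresholded against its own zero-TPM percentile (the whole-cell
threshold would be systematically too high for single-channel scores),
so a gene can be a compartment hit without being a whole-cell hit.
Nontargeting guides serve only as the rank test's control arm and never
enter the null set; zero-TPM genes (TPM exactly 0; threshold
configurable) serve only as the FDR null — the two-control design that
separates "different from controls" from "above the noise floor of
cutting a silent locus". Fewer than 1/FDR null scores triggers a
coarse-threshold warning.

## Retrieval

Cosine similarity; ties broken by stable input order (siblings before
controls). The average-precision increment is ΔRₖ = Rₖ − Rₖ₋₁: recall
is non-decreasing in k, so this is the only sign convention under which
AP is nonnegative and equals the usual non-interpolated AP. AP is
checked against a brute-force sort-and-count oracle to 1e-12, and
exchangeable groups are checked against the analytic permutation null.

## Benchmarks, feature screens, clustering

Complex retention compares the hit fraction of a complex's subunits to
1/3 with exact rational arithmetic (2 of 6 qualifies). Correlation bins
are fixed to [−1, 1] (eight equal, right-closed bins) rather than data
min/max, for comparability across screens. Essentiality uses strict
`dependency < −0.5`; the boundary value is nonessential.

Single-feature screens reuse the hit-calling p-values (two-sided, for
consistency). The top-20+ rule returns every gene with p ≤ the 20th
gene's p, so ties extend the list and its size is ≥ 20 whenever 20
genes were tested. Enrichment is the one-sided (greater) Fisher exact
test — enrichment semantics — with BH-adjusted p-values and an
additional Bonferroni column reported side by side; significance is
called on the Bonferroni column at 0.05. Granularity spectra are read
from normalized but *not* feature-selected gene profiles, since
selection removes most of a redundant granularity ladder.

Ward ordering runs on Euclidean distances between correlation-matrix
rows (clustering the correlation structure, not raw profiles); leaf
order is deterministic with ties resolved by input order, and optimal
leaf ordering is off by default (not part of the standard clustermap
behaviour this mirrors). Diagonally merged heatmaps restrict to genes
hit in both screens, order both triangles by one screen's Ward order,
and are lossless: both input matrices are reconstructable from the
triangles.

## Barcode libraries

The designer selects greedily in seeded-shuffled pool order —
mirroring selection from pre-existing guide designs rather than global
optimization — accepting a candidate when (a) its 12-base prefix keeps
Levenshtein distance ≥ 2 to every accepted barcode, (b) its 11-base
prefix is unseen, and (c) it does not push any base's per-position
frequency to the 0.40 band ceiling once 20 barcodes are accepted (a
soft balance rule; the 0.15–0.40 band quantifies "balanced composition"
since no published figure exists). For equal-length strings an edit
distance ≤ 1 is achievable only by identity or one substitution, so the
distance-2 screen reduces to Hamming distance and vectorizes; the
verifier reports true minimum edit distances via an all-pairs
vectorized DP, cross-checked against the scalar DP and an independent
alignment library in tests. The decoder is detect-only: distance 2
guarantees detection of any single error but not correction, so
non-exact prefixes are rejected, never rescued to a nearest neighbour.

## Problem sizes and limitations

The test suite and acceptance script run entirely on synthetic screens:
a 2,000-gene screen (601 nontargeting guides, 500 zero-TPM nulls,
~1M cells) for FDR calibration; 100–200-gene screens for planted-
recovery, complex-correlation and granularity analyses; 10⁶ simulated
null feature-tests for type-I error; 500-barcode libraries from
5,000-candidate pools. These sizes were chosen so each analysis
completes in seconds to a couple of minutes on one CPU while keeping
≥ 100 null genes wherever a 1% order-statistic threshold is taken.

Passing tests demonstrate the pipeline's statistical guarantees (FDR
control by construction, conservative per-feature type-I error,
selection and retention bounds, barcode distance guarantees) and its
ability to recover planted structure under the generator's assumptions.
They do not certify behaviour under real-data pathologies the generator
omits: non-Gaussian heavy-tailed features, segmentation artifacts,
cell-density and cell-cycle covariates, spatial autocorrelation within
wells, barcode-calling errors correlated with phenotype, or expression
annotations that misclassify the null set. The discrete Mann–Whitney
test with 4 guide units also imposes a hard floor on attainable
p-values when any guide is inactive — profile scores degrade quickly
with Cas9 efficiency, which is a property of the design the synthetic
screens reproduce, not an artifact.
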