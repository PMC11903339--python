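# opscreen

Analysis pipeline for **optical pooled CRISPR screens** with image-based
morphological profiling. In these screens, every cell in a pooled
knockout library is imaged with a five-channel Cell Painting-style panel
(DNA, ER, actin, mitochondria, Golgi/membrane via WGA) and its guide
barcode is read out by in situ sequencing, giving a guide-resolved table
of thousands of morphological features per cell. `opscreen` takes such
tables from single cells to biology:

- **Profiles** — median aggregation by guide and plate, per-plate
  standardization, redundancy-aware feature selection (pairwise
  Pearson |r| ≤ 0.9), gene-level aggregation, and PCA to ≥ 90% variance.
- **Hit calling** — per feature, the guides targeting a gene are
  compared with nontargeting control guides by a two-sided
  Mann–Whitney U-test. The *profile score* of a gene counts features
  with p < 0.001; hits are genes whose score strictly exceeds the
  corresponding order statistic of unexpressed (zero-TPM) genes — an
  empirical null that absorbs nonspecific CRISPR-cutting effects — at a
  chosen FDR (hits at 1% FDR sit above 99% of zero-TPM scores). The
  same machinery called per channel yields *compartment hits*; the
  *morphological signal score* Σ −log₁₀ pᵢ over significant features
  ranks genes for enrichment analyses.
- **Retrieval (mAP)** — profile strength as mean average precision:
  each of a gene's M guide profiles queries its M−1 siblings against N
  control profiles by cosine similarity, with
  APᵢ = Σₖ Pₖ·(Rₖ − Rₖ₋₁), Pₖ = TPₖ/k, Rₖ = TPₖ/(M−1), and
  mAP = (1/M)·Σ APᵢ.
- **Benchmarks** — within-protein-complex correlation vs background
  (complexes retained when ≥ 1/3 of subunits are hits), link-score
  distributions in eight profile-correlation bins, essentiality splits
  at a dependency score of −0.5, and cosine-similarity rankings (.rnk)
  for preranked enrichment tools.
- **Single-feature screens** — "top 20+" most-perturbed gene lists per
  feature (ties at the 20th gene's p-value extend the list), one-sided
  Fisher exact gene-set enrichment with Benjamini–Hochberg and
  additional Bonferroni correction, and granularity spectra that expose
  compositional mass shifts across erosion sizes.
- **Clustering** — Pearson correlation matrices, Ward-linkage leaf
  orders, and diagonally merged heatmaps that show two screens'
  correlations under one gene order.
- **Library design** — greedy selection of guide barcodes that are
  fully deconvolvable within 11 bases and pairwise Levenshtein
  distance ≥ 2 over 12-base prefixes (single-error detection), with an
  exhaustive verifier and a detect-only decoder.
- **Synthetic screens** — a seeded generator producing single-cell
  tables with the structure real screens have (≈4 guides/gene,
  overdispersed cells per guide, nontargeting controls, zero-TPM nulls,
  compartment-concentrated planted effects, complex-correlated effect
  directions, variable guide activity, plate effects, conservation-
  constrained granularity features) plus matching complex/link-score/
  gene-set/expression/dependency annotations, so every stage above is
  testable at desk scale with no external data.

## Worked example

```python
import opscreen as op

cfg = op.ScreenConfig(n_genes=200, n_nontargeting=80, n_plates=3,
                      cells_per_guide_mean=60, frac_zero_tpm=0.5,
                      frac_hit_genes=0.15, effect_size=2.0, seed=7)
screen = op.generate_screen(cfg)
proc = op.process_cells(screen.cells)          # aggregate -> normalize -> select
scores = op.score_screen(proc.guide)           # Mann-Whitney per feature
table = op.scores_frame(scores)
truth = screen.truth.genes.set_index("gene")
nulls = [g for g in truth.index[truth.zero_tpm] if g in table.index]
hits = op.call_hits(table, nulls, fdr=0.01)    # empirical zero-TPM threshold
maps = op.screen_map_scores(proc.guide)        # per-gene mAP
```

prints, summarized:

```
cells: 54,408   guides: 880
features retained after selection: 152 of 152
whole-cell hits: 31   compartment-only hits: 4
whole-cell threshold (1% FDR): 4 significant features
mean mAP, planted hits: 0.851
mean mAP, zero-TPM nulls: 0.130
           profile_score  signal_score  whole_cell_hit
GENE00055             57         297.5            True
GENE00044             53         284.0            True
GENE00001             53         280.9            True
```

The 1% FDR threshold of 4 means a gene must differ from the
nontargeting controls in more than 4 features (at p < 0.001 each) —
more than 99% of the unexpressed null genes do — before it is called a
whole-cell hit. Planted hit genes retrieve their sibling guides with a
mean mAP of 0.85 against the nontargeting background; null genes sit at
the chance level. Four genes are compartment hits without being
whole-cell hits: their signal is confined to one channel's feature
subset (here, the planted lysosomal-acidification-like group, visible
as a loss of WGA granularity at the smallest erosion size with
compensatory gains at larger sizes).

A thin CLI mirrors the library:
`opscreen simulate | profile | call-hits | map-score | design-library |
verify-library | decode | feature-screen | cluster` (see `--help`).

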