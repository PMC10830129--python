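# Methods

This note defines the model implemented by `predict_ct`, records parameter
defaults and the reasoning behind them, and describes what the synthetic
generator does and does not emulate.

## 1. Preferential expression

Input is a genes × cells count matrix with per-cell tissue and cell-type
labels. Per tissue:

1. **Normalisation.** Each cell's counts are scaled to a common library
   size and log-transformed: `norm = log1p(count × scale / cell_total)`
   with `scale = 1e4`. Cells with zero total counts are an error by
   default (`drop_zero_cells=True` discards them instead), because a
   silent division by zero would propagate NaNs.
2. **Expressed-gene filter.** A gene is kept if its normalised value is
   ≥ `min_value = 0.05` in ≥ `min_frac = 10%` of the cells of at least
   one cell type. Both bounds are inclusive. This removes genes whose
   apparent cell-type pattern would be sampling noise around zero.
3. **Averaging.** Normalised values are averaged per cell type. A warning
   is emitted for cell types with fewer than 10 cells, where the average
   is unstable.
4. **Peak filter.** Genes are retained only if their maximum per-cell-type
   average strictly exceeds the median of all entries of the averaged
   matrix. This concentrates the analysis on genes that are clearly
   expressed somewhere in the tissue.
5. **Z-scoring.** Each retained gene's averages are standardised across
   the tissue's cell types (population SD, `ddof = 0`; zero-variance
   genes are dropped and reported). A tissue needs at least two cell
   types; otherwise "relative to the rest of the tissue" is undefined and
   the pipeline raises an error.

Rows and columns are sorted lexicographically so that all downstream
outputs are byte-reproducible.

## 2. Disease scoring

For disease d with gene set G in tissue T, the score of cell type c is the
median preferential expression `median{ P(g, c) : g ∈ G ∩ retained(T) }`.
The median (rather than the mean) keeps a single outlier gene from
dominating a small gene set. Diseases whose catalog genes are entirely
absent from the retained universe are reported with a
`no_expressed_genes` note rather than silently dropped.

**Null distribution.** Each of `reps = 1000` repetitions draws one random
gene set of size |G ∩ retained(T)| without replacement from the retained
universe and scores it in *all* cell types of the tissue, so the null
respects the gene-gene correlation structure of the tissue. The p-value is
the plain fraction of null scores ≥ the observed score. A `plus_one`
option switches to the (k+1)/(reps+1) estimator, which never returns an
exact zero; the plain fraction is the default because it is the natural
Monte-Carlo estimate and makes the exhaustive and sampled modes agree in
expectation. For universes small enough that all `C(universe, n)` subsets
fit within a 2×10⁶ cap, `exhaustive=True` enumerates them and the p-value
is exact.

**Multiple testing and calling.** P-values are Benjamini–Hochberg adjusted
within each disease (across the cell types of each affected tissue), and a
cell type is called *likely affected* when score ≥ 1 (at least one
population SD above the tissue mean, inclusive) and FDR < 0.1 (strict).
With `subset_by="function_label"` the catalog's gene-function annotations
(e.g. ligand vs receptor) are scored as independent subsets, each with its
own null of matching size, so a disease can implicate different cell types
through different gene functions.

Randomness flows through a single integer seed; derived generators are
spawned deterministically, so identical seeds give byte-identical outputs
(checked in the acceptance suite).

## 3. Cross-dataset cell-type matching

Markers of a cell type are genes with preferential expression Z ≥ 2
(inclusive). Across species, marker sets are translated through an
ortholog map by taking the union of images (many-to-many maps are allowed;
unmapped markers are counted and reported). Similarity between cell type a
(dataset A) and b (dataset B) is the Jaccard index of the marker sets.

A pair is **matched** when its Jaccard index is ≥ 0.05 and lies in the top
decile of all pairwise values of the comparison. The percentile rank of a
value j is defined as the fraction of all pairwise values ≤ j (computed
via sort and binary search). This empirical definition — rather than an
interpolated quantile — guarantees that every matched pair genuinely
occupies the claimed top fraction even under heavy ties and small
comparison tables. `rematch_excluding_genes` re-runs matching without a
chosen gene set and reports the concordance of match calls, to check
robustness of a correspondence to, e.g., the disease genes themselves.

## 4. Validation

- **Literature co-appearance.** Given per-tissue record sets for diseases
  and cell types, each (disease, cell type) pair is tested for
  co-appearing in more records than chance by a one-sided Fisher exact
  test (χ² optional) over the universe of the tissue's records. Pairs
  with fewer than 3 joint records are excluded, and p-values are
  Bonferroni-corrected per tissue; a pair is *supported* when the
  adjusted p < 0.001.
- **Enrichment.** The overlap between likely calls and a gold-standard
  pair set is tested by a one-sided Fisher exact test over the evaluated
  universe.
- **Error-rate curves.** For a grid of FDR cutoffs, FPR =
  |predicted∖gold| / |universe∖gold| and FNR = |gold∖predicted| / |gold|.
- **Matched-score correlation.** Spearman correlation of disease scores
  between matched cell-type pairs versus non-matched pairs; agreement of
  the model across datasets should concentrate in matched pairs.
- **Matching permutation test.** Whether likely cell types of shared
  diseases correspond across datasets more often than chance, by
  redrawing one side's likely sets at random. An exact mode computes the
  null by a Poisson-binomial convolution of per-disease hypergeometric
  miss probabilities; the default samples. P-values are BH-adjusted
  across tissue pairs.

## 5. Susceptibility and cell classes

Susceptibility of a cell type = fraction of its tissue's diseases that
call it likely affected; prevalence = fraction of the tissue's cells it
contains. Class-level analysis: one-way ANOVA of susceptibility across
cell classes (reported as F = 0, p = 1 when there is no variation at all,
where the textbook statistic is 0/0), two-sided Mann-Whitney U of each
*prevalent* class against all other cell types with BH adjustment, and
the Pearson correlation of susceptibility with prevalence. Prevalent
classes are those represented by more than 15 cell types across at least
4 tissues, recomputed from the input table.

## 6. Synthetic-data generator

The generator exists to provide planted ground truth for testing, at
problem sizes the package chooses itself.

- **Counts.** Negative-binomial per gene × cell type
  (`dispersion = 2.0`); gene base means are log-normal (median
  `base_mean = 0.05`, `mean_sigma = 2.0`), giving the right-skewed
  expression distribution and the substantial zero fraction typical of
  droplet data. Planted genes use a tighter mean spread
  (`planted_mean_sigma = 0.5`) so their fold effects are not drowned by
  the base-mean lottery. With these defaults the expressed-gene filter
  retains roughly half to two-thirds of genes, i.e. the filter is doing
  real work rather than passing or removing everything.
- **Structure.** Defaults: 2 tissues × 10 cell types × 50 cells, 400
  genes, 10 diseases with 3–10 genes each. Each cell type gets 10
  exclusive marker genes at `marker_fold = 5`. Each disease is planted in
  one (tissue, cell type) by elevating its genes there.
- **Effect size.** The planted fold is `1 + effect_z²`. For a gene
  elevated in exactly one of C cell types, the population Z-score of a
  one-hot elevation saturates at √(C−1); the fold is parameterised so
  that the realised Z approaches `effect_z` before saturation, and the
  default C = 10 makes the default `effect_z = 3` attainable
  (√9 = 3). `effect_z = 0` gives fold 1, i.e. an exact null.
- **Species pairs.** A linked pseudo-dataset shares the planted structure
  under renamed genes with a one-to-one ortholog map; `ortholog_noise`
  scrambles a fraction of map targets by a cyclic shift (guaranteeing no
  accidental fixed points), degrading planted marker overlap.
  `multi_context_diseases` splits a disease's genes into ligand/receptor
  function labels planted in two different cell types, exercising
  subset scoring.
- **Literature.** Record sets with base membership probability
  `p0 = 0.05` over 500 records per tissue; planted pairs receive
  `round(3 × (signal − 1))` extra shared records.

Deliberately **not** emulated: batch and donor effects, ambient RNA,
doublets, cell-type abundance imbalance, dropout beyond what the NB
produces, gene-gene co-expression modules, and phylogenetically realistic
ortholog structure. Conclusions about robustness to those phenomena
cannot be drawn from this generator.

## 7. Limitations

- Preferential expression is relative within a tissue: a gene uniformly
  essential to all cell types of a tissue will not flag any of them.
- The permutation null conditions on gene-set size only, not on
  expression level or GC-like covariates of the disease genes.
- Median scoring needs a handful of genes to be stable; single-gene
  diseases reduce to that gene's Z-score.
- The likely-call thresholds (score ≥ 1, FDR < 0.1) are conventions, not
  optimised values; the error-rate curves exist to make their
  consequences visible.
- Literature co-appearance inherits the biases of whatever record corpus
  it is given; support and truth are not the same thing.
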