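# Methods

## Data model and normalization

The unit of analysis is an annotated cells × genes expression matrix
(`ExpressionStore`, backed by `AnnData`); exactly one cell-type label per
retained cell is an input contract — cells without a label (or labelled
`NA`) are dropped, never imputed. Gene symbols are uppercased on load so
that human panel symbols match mouse datasets by case-insensitive equality
(human `SOD1` ↔ mouse `Sod1`); no ortholog table is consulted. This is a
deliberate simplification: paralogs or species-specific symbols silently
drop out of a panel, and the per-panel drop report should be inspected when
working across species.

Raw counts are CPM-normalized per cell (each cell sums to 10⁶) before both
statistics. Library-size differences otherwise inflate per-cell fold-change
spread and would masquerade as low strictness; the simulator's log-normal
depth factor exists precisely to exercise this (its effect should vanish
after CPM). `--no-normalize` preserves input values for parity experiments
with externally normalized data.

## Specificity and bootstrap enrichment

Per-type mean expression is the arithmetic mean over each type's cells
(types under `min_cells_per_type`, default 10, are dropped). Specificity is
the row-normalized type-mean profile; genes with zero total mean are
flagged unusable and excluded from both target panels and the null
universe. The enrichment null draws same-size gene lists without
replacement from **all** usable genes — target genes are not excluded,
matching the standard expression-weighted enrichment default — and the
p-value carries a +1/(n_boot+1) pseudo-count so it is never 0; ties count
toward the tail (conservative). The FDR family is the cell types of one
dataset × one panel. `size_power_scan` maps detectability against panel
size by rerunning the test on random sub-panels (the spread of real panel
sizes, roughly 5–60 genes, is the intended range).

## Strictness

Strictness is `S = 1/sd(C)` with `C_i = E_i/Ē` and the sample SD (n−1
denominator) over a population's cells. The fold-change reference `Ē` is
ambiguous when a statistic described "in one cell type" divides by "the
mean expression in all cells"; both readings are implemented:

* `global-ref` (default): `Ē` over all cells, spread over the queried
  population — "how strictly does this gene hold its dataset-wide level in
  motor neurons". Population and reference scopes are recorded in output
  metadata.
* `within-type`: `Ē` over the population itself, making S the inverse
  within-population coefficient of variation.

S is scale-invariant (multiplying a gene's expression by k > 0 cancels),
verified to machine precision in the tests. Genes with `Ē = 0` are
unusable; genes whose fold-change SD falls below ε = 1e-12 are flagged
degenerate and reported as S = 1/ε. Both classes are excluded
symmetrically from target panels and the bootstrap universe so that a few
constant genes cannot dominate panel means.

The gene-set test compares the panel's mean strictness with 10,000
bootstrap means of random same-size gene sets; the normal fit uses the
maximum-likelihood estimators (sample mean; SD with the 1/N denominator),
and the p-value is the one-sided upper tail — only *high* strictness
(dosage sensitivity) is called. Bonferroni's family is the number of
populations tested per panel; at the meta level it is the pooled cell-type
count across datasets (two-level correction: FDR within a dataset's
enrichment stage, Bonferroni at the meta stage).

**Adequacy of the normal approximation.** Each test also reports
`empirical_p`, the direct bootstrap tail proportion. On populations whose
strictness distribution is only mildly skewed the two agree within ±0.003
across the 0.01–0.99 range (measured on a 2,000-gene homogeneous-dispersion
simulation, 50,000 bootstrap means of 30-gene sets). When the strictness
distribution is strongly right-skewed — e.g. a mixture of sharply distinct
dispersion classes — the normal tail deviates by up to ~0.02 for 30-gene
panels; in that regime `empirical_p` is the safer number and is provided
for exactly this reason. Extreme z-scores where the empirical tail is empty
rely on the normal extrapolation unavoidably.

## Meta-analysis

Unweighted Stouffer combination of one-sided bootstrap p-values is the
default (`z_k = Φ⁻¹(1−p_k)`, `z = Σw_k z_k/√Σw_k²`); it preserves
direction-consistency of upper-tail evidence, which Fisher's method (kept
behind `method="fisher"`) does not. Bootstrap p-values of exactly 1 (or a
clamped 0) are moved to the [1e-15, 1−1e-15] interior with a warning before
the probit transform. Cell-type labels are harmonized only through an
explicit (dataset, local label) → harmonized label mapping; no fuzzy
matching. Pairs present in fewer than two datasets are excluded, and the
Bonferroni family is the summed per-dataset cell-type count (e.g. four
spinal-cord datasets contributing 14 + 14 + 10 + 18 = 56 tests).

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any
particular tissue: `n_cell_types` populations (real atlases span ~5–75),
negative-binomial counts with per-gene dispersion θ (variance m + m²/θ),
per-type marker genes with `marker_fold`-elevated means, designated strict
(high θ = 5) and tolerant (low θ = 0.5) gene classes disjoint from the
markers, and log-normal per-cell depth (σ = 0.3). Defaults — 5 types × 200
cells, 2,000 genes, 25 markers/type, 5× marker fold, baseline mean 2
counts, background θ = 2 — give sparse overdispersed counts of realistic
magnitude while keeping a laptop-scale footprint; the θ ratio of 10 between
strict and tolerant classes is the separation regime the strictness screen
is designed for. `dispersion_background` accepts a (low, high) range for a
log-uniform per-gene θ continuum (used for rank-recovery checks), and
`assignment_seed` decouples ground-truth structure from count noise so
that independent cohorts with shared biology can be simulated for
meta-analysis. `marker_fold = 1` with zero strict/tolerant genes (the
`.null()` variant) yields an exchangeable null on which both tests' p-values
are verifiably uniform.

What the generator does **not** emulate: batch effects, zero inflation
beyond NB sparsity, cell-type abundance skew, doublets, or real marker
co-expression structure. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery, not robustness to every
artifact of real atlases.

## Validation suite and problem sizes

`scripts/acceptance.py` (and the mirroring tests) measure: exact panel
overlaps of the bundled reconstructions; bootstrap agreement with
exhaustive enumeration of all C(12,4) subsets on a 12-gene toy; type-I
calibration with 500 random 20-gene panels on a null simulation (KS
uniformity and the fraction below 0.05), using 2,000 bootstrap replicates
per panel; ground-truth recovery over 100 default-size replicates with
1,000 bootstrap replicates per call; scale invariance; Spearman rank
recovery of true inverse dispersion on a 500-cell θ-continuum population;
and the CLT-vs-empirical tail comparison at 50,000 bootstrap means. The
reduced bootstrap depths in the repeated-simulation measurements keep the
whole suite at single-digit minutes on one CPU; single-call analyses
default to the full 10,000 replicates.

## Known limitations

* Symbol-equality cross-species mapping (no orthologs); curation aliases
  are not resolved.
* Strictness depends on the normalization applied; CPM is the supported
  default and comparisons across differently normalized datasets are not
  meaningful.
* The CLT p-value degrades for small panels on heavily skewed strictness
  distributions (see above); `empirical_p` is reported alongside.
* The bundled disease panels are labelled synthetic reconstructions, not
  the original curations; analyses of real data should supply curated
  panel files.
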