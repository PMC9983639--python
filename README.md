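# strictscreen

Which cell types does a disease gene panel point at, and how tightly do
those genes have to hold their expression there? `strictscreen` answers
both questions for annotated single-cell RNA-seq data. It was built around
motor-neuron-disease genetics — panels of ALS, HMN, SA, SPG and SMA genes
scored against brain, spinal cord and muscle cell atlases — but applies to
any gene panel and any annotated expression matrix.

The package provides, as a plain Python library with a thin CLI:

* **Expression-weighted cell-type enrichment.** The *specificity* of gene
  *g* in cell type *t* is
  `spec[g,t] = mean_t(g) / Σ_t' mean_t'(g)`, the proportion of the gene's
  summed per-type mean expression found in *t* (rows sum to 1). A panel's
  summed specificity in each cell type is compared against 10,000 random
  same-size gene lists drawn from all expressed genes; the upper-tail
  bootstrap p-value `p = (1 + #{null ≥ observed}) / (n_boot + 1)` is
  FDR-adjusted (Benjamini–Hochberg) across cell types.
* **Strictness**, a per-gene dosage-requirement statistic. With per-cell
  fold changes `C_i = E_i / Ē`, strictness is the inverse sample standard
  deviation

  `S = 1 / sqrt( Σ_i (C_i − C̄)² / (n − 1) )`.

  A dosage-sensitive gene (e.g. a haploinsufficient one) must sit in a
  narrow expression band, so its fold changes barely spread and S is high;
  a loss-of-function-tolerant gene spreads widely and S is low. Gene-set
  significance uses the Central Limit Theorem: the panel's mean strictness
  *x* is compared against the means of 10,000 random same-size gene sets,
  whose distribution is fitted as N(μ, σ²) by maximum likelihood, giving
  `p = 1 − Φ((x − μ)/σ)`; p-values are Bonferroni-adjusted.
* **Meta-analysis.** Per-dataset enrichment p-values for the same
  (cell type, panel) pair are combined with Stouffer's method
  (`z = Σ z_k / √k`), Bonferroni-corrected over the pooled cell-type count
  of all datasets.
* **A synthetic single-cell generator** (negative-binomial counts,
  per-type marker genes, designated low-/high-dispersion gene classes,
  log-normal library-size variation) with known ground truth, so every
  stage is testable without downloading an atlas.

Six bundled gene panels (32 ALS-pathogenicity, 48 ALS-susceptibility,
36 HMN, 15 SA, 20 SMA, 57 SPG genes) are synthetic reconstructions from
public OMIM/GWAS knowledge — see `strictscreen/data/__init__.py`.

## Worked example

`examples/03_strictness_screen.py` simulates a 5-cell-type dataset in which
100 genes are planted as tightly regulated ("strict", NB dispersion θ = 5)
and 100 as overdispersed ("tolerant", θ = 0.5), then screens both panels:

```
        panel cell_type  n_genes  observed_mean  null_mu  null_sigma         p    p_bonf
  strict-like      CT00      100          1.121   0.9705     0.02106 4.486e-13 8.971e-13
  strict-like      CT01      100           1.16    1.006     0.02175 7.763e-13 1.553e-12
tolerant-like      CT00      100         0.6135   0.9705     0.02076         1         1
tolerant-like      CT01      100         0.6507    1.006     0.02155         1         1
```

The strict panel's mean strictness (1.12) sits ~7σ above what random
100-gene panels achieve (μ = 0.97, σ = 0.021), so it is flagged as
dosage-sensitive in both populations; the tolerant panel sits far below the
null mean and is not. The other examples cover panel overlaps
(`01`, e.g. the five genes shared by the ALS pathogenicity and
susceptibility panels: C9ORF72, KIF5A, NEK1, SOD1, TBK1), bootstrap
enrichment (`02`), Stouffer meta-analysis across two simulated cohorts
(`04`), and the one-config full pipeline with its reproducibility manifest
(`05`). Each script prints the numbers it computes and a comment on how to
read them.

## Command line

```sh
strictscreen simulate --out sim/ --seed 1
strictscreen enrich --matrix sim/matrix.mtx --genes sim/genes.txt \
    --cells sim/cells.txt --annotation sim/annotation.tsv \
    --panel panel.txt --n-boot 10000 --seed 1 --out enrichment.tsv
strictscreen strictness --matrix ... --panel panel.txt --all-celltypes --out strictness.tsv
strictscreen meta --results enr_a.tsv --results enr_b.tsv --out meta.tsv
strictscreen run --config run.yaml         # the whole pipeline
```

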