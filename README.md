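# cellregvar

Cell type-resolved analysis of noncoding regulatory variants.

Most disease-associated variants fall outside coding regions, and their
effects on gene expression are both obscured by the mixture of cell types in
bulk tissue and smeared across linkage-disequilibrium (LD) blocks.
`cellregvar` implements an analytical framework that attacks both problems
at once, for computational geneticists who have bulk cohort data (genotypes
and expression), single-cell reference profiles, and GWAS summary
statistics:

1. **Per-cell-cluster expression models.** Each gene is represented by a
   grid of chromatin-feature predictions (by default 2002 tracks x 200
   bins of 200 bp over a ±20 kb window centered on the TSS — 400,400 inputs
   per gene). A regularized boosted-linear model maps the flattened grid to
   log expression of one cell cluster, with genes on a held-out chromosome
   (chr8 by default) measuring generalization via Pearson correlation.
2. **In-silico mutagenesis.** A variant's footprint is the
   alternative-minus-reference difference of its chromatin grid, Δ.
   Projecting Δ through cluster model weights w_c gives a per-cluster
   effect w_cᵀΔ; a one-tailed Welch t-test on |effects| (focal cell type's
   clusters vs all others) scores cell-type specificity, and variants with
   max |effect| > 0.5 are ranked by that test to form each cell type's
   functional variant set.
3. **Interaction eQTLs.** In a bulk cohort with estimated cell-cluster
   fractions f, every cis variant (MAF ≥ 0.05, ±1 Mb of the TSS) is tested
   with OLS:

   `expression ~ β1·(dosage × fraction) + β2·dosage + β3·fraction + covariates`

   The interaction p-value of the top variant per gene is
   Bonferroni-corrected by the eigenvalue-based effective number of
   independent cis tests and Benjamini–Hochberg adjusted across genes.
4. **LD integration.** Predicted functional variants in high LD
   (r² > 0.8) with candidate top (i)eQTLs (FDR < 0.4) become variant–gene
   links, combining sequence-based prediction with population-genetic
   support.
5. **Downstream.** Approximate-Bayes-factor colocalization (PP.H0–H4),
   single-causal 95% credible sets, variant-to-function mapping of GWAS
   loci, stratified-heritability annotation output, and the enrichment
   statistics used to benchmark all of the above (matched nulls, bootstrap
   fold differences, permutation enrichment, Fisher exact, recovery-curve
   AUC).

A seeded synthetic-data module (`cellregvar.simulate`) generates every
input with known ground truth, so the full chain is exercisable and
testable without any external download.

## Worked example

Run the whole chain on generated data:

```python
from cellregvar.pipeline import PipelineConfig, run_pipeline

metrics = run_pipeline(PipelineConfig(seed=1), "run")
print(metrics)
```

which prints (exactly reproducible for this seed):

```
{'median_holdout_pcc': 0.9997426140116152,
 'n_functional_variants': 12,
 'n_candidate_qtls': 6,
 'n_integration_links': 7,
 'integration_recall': 1.0,
 'integration_precision': 1.0,
 'n_gwas_regions': 2,
 'n_v2f_mappings': 2,
 'seed': 1}
```

Reading the numbers: the per-cluster expression models reach a median
holdout Pearson correlation of 0.9997 on chromosome-8 genes (the synthetic
truth is nearly noiseless, so this mainly checks the trainer); 12 variants
pass the |effect| > 0.5 specificity screen; all 6 planted interaction eQTLs
survive FDR < 0.4; and the r² > 0.8 merge recovers every planted
variant–gene pair (recall and precision 1.0) with 7 links total. Two GWAS
regions reach p < 1e-5, and 2 functional variants fall inside their 95%
credible sets (the variant-to-function mappings).

The same pipeline is available from the shell:

```bash
cellregvar run-all --seed 1 --out run/
```

and each stage separately (`simulate`, `train`, `predict-effects`,
`specificity`, `select`, `map-ieqtl`, `integrate`, `coloc`, `finemap`,
`map-v2f`, `enrich`, `annotate-ldsc`).

## Documentation

See `docs/methods.md` for the statistical models, default parameters, the
design decisions behind the synthetic-data generators, and known
limitations.
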