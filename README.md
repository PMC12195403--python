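# pm3 — Personalized Metabolic Margin Mapping

`pm3` screens a curated, annotation-rich metabolic gene panel for **subtle,
coordinated transcriptional divergence** between two groups of samples
(e.g. disease vs control cortex).  It is aimed at the regime where
conventional differential-expression pipelines have little to say: small
cohorts (on the order of 12 vs 12), effect sizes of a few percent, and a
hypothesis that lives at the level of biochemically linked gene sets
(cofactor dependencies, subcellular compartments, metabolic domains)
rather than single genes.

Users supply three tab-separated inputs: a normalized gene × sample
expression matrix (e.g. TPM), a sample label table (`case` / `control`),
and a gene panel annotated with enzyme name, metabolic domain, pathway,
cofactor tags and compartment.  The package ships a 26-gene panel of
TCA-cycle, transamination, one-carbon, sulfur and energy-buffering enzymes
plus vitamin transporters as a working fixture; real analyses bring their
own panel.

## Method

For each panel gene *g* with case samples *x* and control samples *y*:

- **Percent expression difference**
  %Δ = 100 · (x̄ − ȳ) / ȳ, the signed effect size on the linear scale;
- **log2 fold change**
  log2FC = log₂(1 + %Δ/100) = log₂(x̄/ȳ);
- **Mean Euclidean distance**
  ED = mean over case samples of |xᵢ − ȳ| (or over all case × control
  pairs), a dispersion-aware divergence;
- **Anomaly AUC** — a one-dimensional **Isolation Forest** (implemented
  from first principles: random axis splits, subsampling ψ, score
  s = 2^(−E[h]/c(ψ))) is trained on the control samples and scores every
  sample; the Mann–Whitney statistic P(s_case > s_control), folded to
  [0.5, 1], measures how well anomaly separates the groups.

Genes are ranked by folded AUC (ties broken by |%Δ|, then symbol), the
genes × samples anomaly-score matrix is clustered with K-means
(silhouette-selected k by default), and the merged report is stratified by
metabolic domain and exploded into a long-format cofactor × compartment
view.  No fold-change or significance threshold is applied anywhere;
an optional Mann–Whitney + Benjamini–Hochberg annotation is available but
never drives the ranking.

A synthetic-cohort generator (`pm3.synthetic_data`) plants multiplicative
shifts (−17%…+30%) on a mean-corrected log-normal background at the 12 vs
12, 158-gene scale, so the whole pipeline is testable end to end without
any external data.

## Worked example

```python
from pm3 import PM3Model
from pm3.synthetic_data import reference_spec, simulate, sim_gene_model

spec = reference_spec(seed=7)          # 158 genes, 12 vs 12, sigma = 0.2
study, truth = simulate(spec)
res = PM3Model(study, sim_gene_model(spec)).fit(seed=7)
print(res.summary(max_rows=6))
```

```
Personalized Metabolic Margin Mapping
======================================================================
genes: 158 panel genes   samples: 12 case / 12 control
forest: 100 trees, seed 7, training=reference_controls
clusters: k=2   AUC > 0.70: 24 gene(s)
----------------------------------------------------------------------
         pct_diff  log2fc  mean_ed   auc  cluster         domain
symbol
CKMT1A     -17.56  -0.279    2.786  0.81        1  mitochondrial
PANK1      -13.32  -0.206    1.242  0.81        1          other
NULL086     22.13   0.288   80.924  0.79        1          other
NULL077      8.69   0.120    7.564  0.78        1          other
NULL096      0.38   0.005   13.090  0.77        1          other
NULL108      0.83   0.012    4.239  0.76        1          other
... (152 more rows)
```

The two strongest planted shifts (CKMT1A −16.9%, PANK1 −11.8%) top the AUC
ranking; `NULL***` genes are unshifted fillers, and their presence among
the 24 genes with AUC > 0.70 is exactly the small-cohort false-positive
rate the anomaly AUC carries at n = 12 vs 12 — the reason the method reads
AUC, %Δ and annotation context together rather than any one number alone.
`res.top_genes()`, `res.stratify_domains()` and `res.cofactor_view()`
return the threshold, domain-stratified and cofactor-long views;
`res.save(outdir)` writes all tables (TSV + JSON with full metadata),
byte-identically across reruns of the same configuration.

The same pipeline runs from the shell:

```bash
pm3 simulate --seed 7 --out cohort/
pm3 run --expression cohort/expression.tsv --labels cohort/labels.tsv \
        --panel cohort/panel.tsv --out results/ --seed 7
```

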