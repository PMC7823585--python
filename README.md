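# panclass

Tumor-agnostic C1/C2 classification of bulk expression cohorts, built from
nearest-centroid intrinsic-subtype calls with permutation-based confidence,
plus the downstream characterization machinery: single-sample gene-set
enrichment, per-cohort moderated differential expression with cross-cohort
consistency counting, signature scoring, tumor–normal paired differences,
Cox survival analysis benchmarked against a random-gene-signature null (the
V-score), class × immune-infiltrate interaction models, and per-drug lnIC50
class models. A synthetic-data module generates multi-cohort RNA-seq-like
datasets so every stage is testable at desk scale.

## How it works

1. **preprocess** — TMM scaling factors (the published trimmed-mean-of-M-values
   procedure), `log2(CPM + 0.5)` transform, a per-cohort low-expression filter
   (discard genes with CPM < 1 in more than half the samples), and per-cohort
   z-scoring.
2. **classify** — each sample's ~50 panel genes are correlated (Spearman by
   default) with four subtype centroids (LumA, LumB, Her2e, Basal); a
   permutation null (shuffling the sample's own panel values, B=10000) gives a
   p-value per subtype, BH-adjusted within the sample. Samples whose
   best-correlated subtype is the unique significant one are *assigned*;
   the rest are *ambiguous*/*unassigned* and excluded. Assigned LumA → class
   C1; assigned LumB/Her2e/Basal → class C2.
3. **enrich** — GSVA-style single-sample enrichment: per-gene kernel-CDF
   statistic across samples, symmetrized ranks, weighted KS-like random walk
   per gene set; rank-sum class tests per cohort.
4. **diffexp** — per-cohort moderated-t differential expression (empirical-
   Bayes variance shrinkage, moments fit on log variances) between C1 and C2
   (cohorts with ≥8 samples per class), then cross-cohort consistency: features
   significant and concordant in ≥30/33 cohorts are "core", in more than half
   are "broad".
5. **signatures** — mean-of-z-scores scoring, the CA20-style sum of
   cohort-standardized expression, paired tumor−normal differences
   D = V_t − V_n, and exact rank tests.
6. **survival** — univariate Cox fit of class (own Newton solver with Efron
   ties, validated against lifelines), the V-score (proportion of 5000
   random-50-gene PCA-median-split classifications whose Cox fit has larger
   |log HR| *and* smaller p than the observed one), and class × infiltrate
   interaction models with a deviance comparison.
7. **drugs** — per-drug two-group linear model of lnIC50 on class with
   Shapiro–Wilk and Brown–Forsythe gates and BH adjustment within cohort.
8. **syndata** — negative-binomial counts with cohort effects and log-normal
   library sizes, subtype-centroid panel genes, a core module upregulated in
   class 2, paired normals, class-dependent survival/drug response, Dirichlet
   infiltrates.

## CLI

Each stage is a `panclass` subcommand operating on plain TSV/GMT/JSON files:

```sh
panclass simulate --out simdir --seed 1
panclass preprocess --counts simdir/counts_cohort00.tsv --out pre
panclass classify --expr pre/logcpm.tsv --centroids simdir/centroids.tsv \
    --out calls.tsv -B 10000 --alpha 0.01 --seed 1
panclass enrich --expr pre/logcpm.tsv --gmt sets.gmt --out scores.tsv
panclass score --expr pre/zscores.tsv --signature sig.txt --out sig_scores.tsv
panclass diffexp --expr pre/logcpm.tsv --classes classes.tsv --out de.tsv
panclass consistency --results de1.tsv --results de2.tsv --min-cohorts 30 --out core.tsv
panclass survival --clinical clinical.tsv --expr pre/logcpm.tsv \
    --out surv.json --vscore-reps 5000 --seed 1
panclass drugs --responses drugs.tsv --classes classes.tsv --out drugs_out.tsv
```

Formats: expression matrices are TSV with genes in rows (first column the
gene id) and a header row of sample ids; gene sets are standard GMT;
signatures are one gene per line with an optional `# {"name": ..., "mode":
"mean_z"|"ca20"}` header; clinical tables need `sample_id`, `time`, `event`,
`class` columns; drug tables need `cell_line`, `cohort`, `drug`, `lnIC50`.

Bundled signatures (`panclass/data/signatures/`): the 4-gene TP53-pathway and
9-gene embryonic-stem-cell lists are included; proliferation/CA20/RB files
are placeholders to be replaced with the published lists.

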