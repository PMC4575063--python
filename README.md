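# coexqtl

Integrative mRNA/miRNA co-expression network analysis for small matched
case–control brain expression studies, with genetic (cis-eQTL) follow-up.

The package is aimed at researchers analyzing postmortem brain (or other
tissue) expression from a modest number of matched cases and controls who
want to go beyond single-transcript statistics: it finds co-expression
modules on both the mRNA and miRNA side, prioritizes hub transcripts, tests
modules for cell-type-marker and pathway enrichment, links miRNA hubs to the
mRNA hubs they likely repress, maps cis-eQTLs for hub genes, and asks
whether those eQTLs carry disease-association signal in an independent GWAS
cohort. A fully specified synthetic-cohort generator with planted ground
truth makes every stage testable end to end without access to restricted
data.

## The model in brief

**Signed weighted network.** For transcripts *i, j* with Pearson
correlation *r<sub>ij</sub>*, the signed similarity is
*s<sub>ij</sub>* = (1 + *r<sub>ij</sub>*)/2 and the adjacency
*a<sub>ij</sub>* = *s<sub>ij</sub>*<sup>β</sup>, with β the smallest
integer whose degree distribution approximates scale-free topology
(R² > 0.80). The topological overlap measure

  ω<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>) / (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),  ℓ<sub>ij</sub> = Σ<sub>u≠i,j</sub> a<sub>iu</sub>a<sub>uj</sub>

turns shared neighborhoods into similarity; 1 − ω is clustered by average
linkage and modules are cut from the dendrogram adaptively, refined by an
eigengene-membership sweep, and merged when eigengenes correlate ≥ 0.8.

**Module statistics.** Each module is summarized by its eigengene (ME, first
principal component); module membership MM<sub>i</sub> = cor(x<sub>i</sub>,
ME) and gene significance GS<sub>i</sub> = |cor(x<sub>i</sub>, trait)| rank
transcripts; hubs are the top quartile of MM within disease-significant
modules (Bonferroni-adjusted ME–trait correlation p ≤ 0.05, confounded
modules removed).

**Integration and genetics.** All miRNA-hub × mRNA-hub Pearson correlations
are tested for sign bias (χ²), negative pairs are filtered at BH FDR ≤ 0.10
and intersected with seed-match target predictions; cis-eQTLs are mapped
within 1 Mb by an additive linear model with covariates (BH FDR ≤ 0.10)
after hard-calling (p > 0.98), MAF ≥ 0.24 and LD (r² ≥ 0.8) filtering; the
significant eQTL set is tested in an external cohort with a SKAT-style
variance-component score test, Q = (y − μ̂)ᵀGGᵀ(y − μ̂), with Simes
correction across phenotypes.

## Worked example

```bash
coexqtl run --out demo --seed 0
```

runs the whole pipeline on the default synthetic cohort (36 samples split
18/18, 3000 mRNA probes in five planted modules — one confounded by brain
pH — 300 miRNA probes in three modules, planted miRNA→mRNA repression,
eight planted cis-eQTLs, and a 1399-subject external GWAS cohort). The run
prints, among others:

```
pipeline complete; outputs in demo
  module_ari_mrna: 0.929
  module_ari_mirna: 0.928
  hub_recall: 0.699
  hub_precision: 0.935
  repression_recall: 0.956
  repression_precision: 0.896
  eqtl_recall: 0.250
```

Reading: module assignments agree with the planted truth at adjusted Rand
index ≈ 0.93 on both platforms; ~94% of selected hubs are planted
top-loading genes; ~96% of planted repression pairs are recovered by the
negative-correlation ∩ prediction intersection at ~90% precision. Hub
recall (~0.70 here) is bounded by the nominal differential-expression
filter and correlation-ranking noise at n = 36 — see `docs/methods.md`.
`demo/` contains per-stage TSV tables (modules, eigengenes, module–trait
correlations, hubs, enrichment, hub-pair correlations, targeting pairs,
eQTLs, set tests), JSON stage metadata, and `recovery_report.json`.

The same stages are available individually (`coexqtl simulate | diffexpr |
network | enrich | integrate | eqtl | settest`) and as library functions
(`coexqtl.coexnet`, `coexqtl.mirnet`, `coexqtl.genetics`, ...).

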