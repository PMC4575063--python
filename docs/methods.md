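# Methods

This note records the models, parameter choices and numerical decisions
behind `coexqtl`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort and planted truth

The generator emulates a small matched case–control postmortem expression
study measured on two platforms, at the *network input* stage: values are
on a standard-normal log2-like scale (array normalization is out of scope),
and nearly all transcripts belong to co-expression modules, mirroring real
module decompositions in which only a residual grey fraction stays
unassigned.

A module-q gene is x<sub>i</sub> = u<sub>i</sub>e<sub>q</sub> +
√(1−u<sub>i</sub>²)ε with iid standard-normal ε, gene loadings
u<sub>i</sub> ~ U(0.3, 0.95), and eigengene e<sub>q</sub> = s<sub>q</sub>
α<sub>q</sub> z + √(1−α<sub>q</sub>²)η, where z is the standardized case
indicator, α<sub>q</sub> ∈ [0.6, 0.8] the module–trait loading and
s<sub>q</sub> = ±1 the direction. By construction cor(x<sub>i</sub>,
x<sub>j</sub>) → u<sub>i</sub>u<sub>j</sub> within a module. Defaults: 36
samples (18/18), five mRNA modules of 900/700/550/450/300 genes among 3000,
and three miRNA modules of 110/90/70 among 300.

Design choices worth calling out:

- **Confounded module.** One mRNA module's driver is an equal mix of
  standardized brain pH and the case indicator. The case component lets its
  genes survive nominal differential-expression filtering; the pH component
  then makes the module significantly pH-correlated so module–trait
  screening flags and removes it — the removal pathway is exercised end to
  end rather than only in a unit test.
- **Repression.** For each planted pair, γ·(miRNA value) is subtracted from
  the target mRNA (γ = 0.6). Repressor miRNA modules carry trait loadings
  of sign opposite to their target mRNA modules (miRNAs up in cases repress
  mRNAs down in cases); pairs are planted between the strongest half of
  each side's hub list. Both choices make recovery at n = 36 a well-posed
  question: the opposite-sign coupling gives planted pairs expression
  correlations near −0.6 to −0.7 rather than the −0.45 they would have with
  independent module drivers.
- **Genotypes.** Dosages are Binomial(2, MAF); planted cis variants
  (MAF 0.35, per-allele effect β<sub>g</sub> = 1.0 on the log2 scale) land
  within 1 Mb of their target hub gene on one synthetic chromosome, decoys
  at least 1 Mb from every target. GEN-style probability triples place
  0.999 on the true class, with a 2% fraction flattened below the 0.98
  hard-call threshold to exercise missingness.
- **External GWAS cohort.** 1399 independent subjects; case status is
  Bernoulli(logistic(β₀ + Σ b<sub>j</sub>G<sub>j</sub>)) with b = 0.5 on
  the first four planted eQTL variants; the symptom count is Poisson with
  log-rate linear in the same score; a log-normal "max drinks" phenotype is
  generated null. Family structure is not simulated, matching the score
  test's independence assumption.

Not emulated: probe-level intensities, batch effects, heavy-tailed
expression noise, LD structure beyond what random binomial draws produce,
population stratification, and matching-induced covariate balance beyond
drawing covariates iid. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to array artifacts.

## Preprocessing

- **PCA outlier flagging** uses leave-one-out projection: components are
  fit on the other samples and the held-out sample's projections are
  z-scored against the training scores; a sample extreme (|z| > k_sd,
  default 4) on ≥ 2 of the first 3 components is flagged. Leave-one-out is
  essential — with the candidate included, PCA rotates one axis onto the
  outlier, and no single aberrant array can be extreme on two components.
- **Covariate screening** regresses each candidate against every transcript
  and retains candidates whose fraction of nominal hits exceeds the α
  expectation by a one-sided binomial test. With strongly co-expressed
  transcripts the hit counts are over-dispersed, so the test is liberal on
  module-structured data; retained covariates only enter the adjustment
  model, where an unnecessary covariate costs one degree of freedom.
- **Differential expression** fits expression ~ case (+ covariates) by IRLS
  with Huber loss (tuning constant 1.345, ≤ 50 iterations, tolerance 1e-8),
  p-values from the t reference with n − k df; ordinary least squares is
  the fallback on degenerate fits. Transcripts at nominal p ≤ 0.05 feed the
  network stage — deliberately no multiplicity correction, to keep smaller
  effects in the network universe.

## Network construction

- β is chosen per platform as the lowest candidate whose signed scale-free
  fit exceeds 0.80. The fit regresses log10 *density* on log10 mean
  connectivity over 10 equal-occupancy bins (equal-occupancy bins make raw
  frequencies constant, so the bin width must be divided out). On pure
  noise no β reaches the target and the maximizer is returned with a
  fallback flag.
- Module detection clusters TOM dissimilarity by average linkage and splits
  the dendrogram top-down: within each branch, candidate cuts are scanned
  and the cut maximizing the number of size-qualified subclusters is
  applied recursively (ties toward the higher cut, which keeps branch
  periphery). This resolves modules that merge with each other below the
  height at which noise attaches — a regime where no single static cut
  works. A final branch is accepted only if its cohesion contrast (mean
  within-branch TOM similarity over mean similarity of members to
  non-members) is ≥ 1.8; members whose individual contrast is below that
  floor are shed first. Measured on the default cohort, genuine modules sit
  at contrast ≥ 2.1 and amorphous noise clusters at ≤ 1.5 across β ∈ [5,
  14], so the floor is scale-free with margin on both sides. A candidate
  spanning the entire input has no outside reference and stays grey. An
  explicit `cut_height` overrides the adaptive scan.
- After detection, modules whose eigengenes correlate ≥ 0.8 merge
  iteratively, then a k-means-style eigengene-membership sweep reassigns
  every transcript to its best-correlated module eigengene subject to a
  kME ≥ 0.2 floor (the common membership convention), recomputing
  eigengenes between passes. The sweep recovers weakly loaded periphery
  that branch cutting leaves grey and corrects cross-module mistakes.
- Eigengenes are first right-singular vectors of the standardized member
  matrix, centered, scaled to unit variance (n − 1 denominator) and
  oriented to correlate positively with the module mean profile.
  Module–trait screening uses Pearson correlations with t-based p-values
  and a Bonferroni factor equal to the number of non-grey modules; modules
  significant for pH, PMI, age or RIN are flagged confounded and excluded
  from the disease-significant list.

## Enrichment

Hubs are the top ceil(0.25·size) transcripts by MM within each
disease-significant module (boundary ties broken by stable input order and
logged); an MM ≥ 0.8 cutoff is available as an additional AND-filter but is
off by default. Probes collapse to gene symbols by maximum MM. Marker
enrichment is a one-tailed hypergeometric test against the network-universe
background with a Bonferroni factor equal to the number of significant
modules. Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum
(weight 1), gene-label permutations (default 1000), sign-stratified NES and
the standard pooled-NES FDR; set sizes are restricted to [15, 500] after
intersection with the ranked universe; leading edges are the set members at
or before the ES maximum (or at/after the minimum for negative ES).

## miRNA:mRNA integration

All hub pairs are correlated on the shared samples; the positive/negative
split is tested by a 1-df goodness-of-fit χ². Targeting candidates are
negative pairs at BH FDR ≤ 0.10, with BH computed within the negative-sign
stratum (a whole-table option exists; the stratum choice changes the
retained count and is recorded in stage metadata). The built-in predictor
is seed-match only: a site is the reverse complement of miRNA positions 2–8
in the 3' UTR, classed 8mer > 7mer-m8 > 7mer-A1 with weights 3/2/1 summed
over sites; no duplex free energy or conservation scoring is attempted, and
externally computed prediction tables are accepted interchangeably. The
targeting table is the inner join of FDR-passing negative pairs with
predictions; cooperative targeting counts distinct miRNAs per target gene.

## Genetics

Hard calls take the argmax class when its probability exceeds 0.98, else
missing; variants with no confident call are dropped. QC applies the MAF ≥
0.24 floor (folded), then greedy sliding-window LD pruning (window 50,
step 5, r² ≥ 0.8, lower-MAF member removed). The cis scan tests every
(variant, transcript) pair within 1 Mb of the gene's nearest edge (1-based
closed intervals) by least squares with per-variant mean imputation of
missing dosages, case status and smoking as covariates, and pools BH across
all cis tests. The set-based test is a variance-component score test with
linear kernel GGᵀ and unit weights under a logistic (binary) or linear
(quantitative) null; the null distribution of Q is the usual weighted sum
of chi-squares, evaluated by exact characteristic-function inversion
(Imhof quadrature; a single eigenvalue short-circuits to a scaled
chi-square) with Liu moment matching as fallback — moment matching alone
is measurably conservative at α = 0.05. Phenotype-level p-values are
combined by Simes (global p = min m·p<sub>(i)</sub>/i, step-up adjusted
values capped at 1). The GEE family-structure machinery of kin-cohort set
tests is deliberately replaced by this unrelated-subject test; the cohort
generator draws independent subjects accordingly.

## Recovery metrics and their ceilings

The pipeline's recovery report compares output with planted truth on the
universe that entered the network stage: adjusted Rand index of module
labels (grey/"none" as its own class), hub recall/precision against planted
top-quartile loadings of non-confounded modules, repression recall/
precision against planted pairs, and planted-eQTL recall among significant
calls.

Two ceilings are worth knowing. First, with 36 samples and loadings down to
0.3, ranking module members by correlation with even the *true* eigengene
recovers on average only ~87% of the planted top-quartile loadings (the
sampling sd of a correlation at n = 36 is ≈ 0.065 near the quartile
boundary), so hub recall near 0.87 means the implementation is at the
information limit, and recall through the additional nominal-DE filter is
correspondingly lower (~0.70). Second, planted-eQTL recall is power-limited:
a β<sub>g</sub> = 1.0 effect at n ≈ 35 yields p ≈ 10⁻³–10⁻⁴, which rarely
survives BH at FDR 0.10 against ~2700 cis tests; the set-based GWAS
enrichment nevertheless detects the planted signal because the external
cohort is 40× larger.

## Problem sizes used in tests

Unit tests run on reduced instances (hundreds of transcripts, 12–60
samples). The acceptance suite uses the full default cohort for module
recovery (10 seeds), 200 replicates of a 200-gene × 2000-variant all-null
scan for eQTL FDR control (50 replicates estimate a ~0.10 rate with a
±0.04 sd, too coarse against a 0.15 bound), 2000 phenotype permutations for
kernel-test calibration, and two complete pipeline runs for byte-level
determinism.
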