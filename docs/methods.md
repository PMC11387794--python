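# Methods

This note documents the statistical models behind `cocusig`, the
parameter defaults and why they were chosen, the numerical conventions,
and what the synthetic generators do and do not emulate.

## Differential ranking and enrichment

Genes are ranked co-culture vs mono-culture by the pooled-variance
two-sample Student t statistic computed on log2(x+1) expression. A
variance floor of 1e-8 is applied to the pooled variance so that
zero-variance genes (common in noise-free synthetic data) produce large
finite statistics instead of infinities; a gene with equal means and no
variance gets metric 0. The ranked list is sorted descending with ties
broken lexicographically by gene id, so rankings are deterministic.

The enrichment score (ES) of a gene set along a ranked list of N genes
is the signed maximum deviation of the weighted Kolmogorov–Smirnov
running sum: each in-set gene increments by |metric|^p normalized by the
in-set total (weight p = 1 by default, the standard "weighted" setting;
p = 0 gives the unweighted statistic, invariant under monotone metric
transforms), and each out-of-set gene decrements by 1/(N − N_hit). If
every in-set weight is zero the hit increments fall back to uniform
1/N_hit so the statistic stays defined. The leading edge is the in-set
genes at or before the extremum (at or after it for negative ES).

**Extremum tie rule.** The positive and negative extrema of the running
sum frequently have exactly equal magnitude (the hit term reaches
exactly 1 at the last in-set gene), and floating-point summation order
would otherwise pick the ES sign arbitrarily. Ties within 1e-12 resolve
to the positive extremum, in the reference implementation, the
vectorized permutation null, and the test oracles alike.

**Permutation null.** Significance uses gene-set permutation: the null
ES distribution of a set of size k is that of random k-gene sets drawn
without replacement from the ranked list (1000 permutations by default;
at least 100 required). Because this null depends only on k given the
ranked weights, the permutation stream is seeded by (seed, k): sets of
equal size share one null, duplicates yield bit-identical results, and
the null is computed once per size. The normalized enrichment score
divides ES by the mean |null ES| of matching sign; empirical p-values
carry +1 smoothing so they are never 0; the FDR q of a set is the ratio
of null to observed tail fractions at its NES within its sign class,
clipped to [0, 1] with a monotonicity pass (a less extreme NES never
receives a smaller q). Sets with fewer than 5 or more than 500 genes in
the ranked list are skipped.

## Signature derivation

*Pathway-frequency route.* Per dataset and cell type, sets with ES > 0
and FDR q < 0.05 count as enriched. The upregulated pool is the union of
their leading edges — the leading edge is enrichment analysis' own
definition of the genes driving a set's signal, which is why it
operationalizes "the upregulated genes" here. A pool gene is kept when
it belongs to at least ceil(0.20 × n_enriched) of the enriched sets,
counted against full set membership (a gene can drive one pathway while
belonging to several); the boundary is inclusive. Kept lists are then
intersected across all datasets of a cell type, and the cancer and CAF
lists are unioned. Tightening either threshold can only shrink the
result.

*Fold-change route.* Per dataset and cell type, genes with linear
co/mono mean ratio ≥ 1.5 (inclusive; +inf ratios count, 0/0 ratios are
excluded) are kept, intersected across the cell type's datasets, and
the two cell-type lists unioned.

Both routes require presence in *all* datasets of a cell type. The
signature's gene list is always the union of the two provenance lists,
so |signature| = |cancer| + |CAF| − |shared|.

## Signature scoring

A sample's score is the mean of per-gene z-scores of log2(x+1)
expression over the signature genes present in the matrix (missing
genes are logged; an all-constant gene contributes 0; standard
deviations use ddof = 1). z-scoring makes the score invariant under
gene-wise affine transforms of the log expression, so quartile
stratification is scale-free. The `SignatureScorer` estimator learns the
per-gene standardization on `fit` and can apply it to new samples with
`transform`; the `score_signature` function is fit-and-transform on one
matrix.

## Contamination model

A sorted co-culture sample is modeled as a convex mixture
s = (1−α)·own_mono + α·other_mono. α is estimated by one-parameter
least squares restricted to the union of lineage marker genes —
carcinoma: CDH1, EPCAM, CD24 plus the KRT prefix family; fibroblast:
COL1A1, COL1A2, DCN, CD248 plus the PDGFR prefix family, both expanded
against the data's gene universe — with the closed form
⟨s − own, other − own⟩ / ‖other − own‖², clipped to [0, 1]. The fit is
declared unidentifiable when the two mono profiles differ by less than
1e-6 in relative norm on the markers. Correction inverts the mixture per
gene on the *linear* scale (mixing is linear in transcript abundance):
corrected = max(0, (s − α·other)/(1−α)), clipping negatives to zero with
a logged count, and refuses α ≥ 0.9 where the inversion amplifies noise
beyond usefulness. On noise-free mixtures the inversion is exact for all
α in [0, 0.9).

## Survival analysis

Quartile groups use type-7 quantile boundaries (numpy's default linear
interpolation, matching R's `quantile`); a score exactly on a boundary
joins the lower group, making stratification deterministic under ties.
Kaplan–Meier estimation, the two-group log-rank test and Cox regression
are delegated to lifelines; Cox models use Efron tie handling (the
modern default). Hazard ratios are exp(β̂) with 95% Wald intervals.
Note that Efron's correction makes the fit *not* exactly invariant to
duplicating every record (duplication creates ties), though the
difference is O(1/n). Spearman correlations use average ranks for ties;
two-group comparisons are equal-variance Student t tests (independent or
paired).

## Multi-region concordance

Regions are labeled high when their score strictly exceeds the
cohort-wide median of region scores (ties to low); the threshold is
exposed as a parameter because the median is a convention, not a
property of the data — in particular, when high and low regions are
imbalanced the median order statistic falls inside one score cluster
and mislabels about half the imbalance even with perfectly separated
clusters, so analyses with a known decision boundary should pass it
explicitly. Patients with ≥ 2 regions are concordant_high /
concordant_low / discordant; single-region patients keep a risk label
but leave the concordance denominator.

Under the chance null each region is an independent Bernoulli(q) high
draw (q = 0.5 for a median split), giving
E[concordant] = Σᵢ [qⁿⁱ + (1−q)ⁿⁱ] over multi-region patients i — the
only reading of "labels vary randomly between regions" with a closed
form. For the Fisher test the expected concordant count is rounded to
the nearest integer and the expected discordant cell is taken as the
complement, so both rows share the multi-region total; the two-sided
p-value sums hypergeometric tables at fixed margins whose point
probability does not exceed the observed table's (scipy's convention).

## Synthetic generators

All generators are pure functions of (config, seed); a single seed
expands into fixed per-component child seeds, so components are
independently reproducible. Noise is multiplicative log-normal
(Gaussian on log2), matching the log-scale analyses downstream.

*Co-culture simulator.* Defaults mirror the analysed design: 3
cancer/CAF dataset pairs × 2 cell types, 4 replicates per condition,
2000 genes, a 30-gene planted program upregulated by log2 fold change
+1.5 in co-culture in both cell types, noise sd 0.2 on log2, and
per-dataset baselines drawn uniformly from log2 expression 3–8. In the
noise-free limit every planted gene's realized fold change is exactly
2^1.5.

*Pathway collection.* `simulate_gene_set_collection` emulates a pathway
database in which the planted program spreads over several overlapping
pathways: 6 "responsive" sets each containing a random 60% of the
program topped up with background genes, and 6 pure-background sets,
all of fixed size 50. Equal sizes mean one permutation null serves the
whole collection, and the overlap structure exercises the ≥ 20%
frequency rule non-trivially (a planted gene appears in ~3.6 of 6
enriched sets; a background member of a responsive set rarely reaches
two).

*Survival simulator.* Event times are exponential with hazard
baseline·exp(β·score + covariate terms); censoring is independent
Uniform(0, c) with c calibrated by bisection so the realized censoring
fraction matches the target. Age/sex/stage columns are always generated
(standard-normal age, Bernoulli sex, uniform stage 1–4 treated as
continuous) with log-hazard effects defaulting to 0. This is the
simplest data-generating process satisfying proportional hazards, which
is all the hazard-ratio recovery checks require.

*Multi-region simulator.* Each patient draws 1–5 regions (mix defaulting
to 20/30/25/15/10%), a latent high label with probability q_patient, and
per-region flips with probability ε; scores come from label-conditional
Gaussians (means ±1, sd 0.3). ε = 0 gives perfectly concordant truth;
ε = 0.5 makes region labels i.i.d. fair coins, the regime in which the
analytic chance expectation must match simulation.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: count-level noise (negative binomial
overdispersion, library-size variation), batch and platform effects,
correlated gene modules beyond the planted program, non-proportional
hazards or informative censoring, and spatially structured rather than
independent region-to-region variability. The pipeline's behavior on
real cohorts additionally depends on normalization upstream of it.

## Other conventions and limitations

- Expression tables are TSV (CSV sniffed) with gene ids first; linear
  matrices must be finite and non-negative. The cohort expression filter
  keeps genes at ≥ min_level in ≥ ceil(min_fraction × n_samples) samples
  (both inclusive, per "at least"); it is idempotent and antitone in
  both thresholds.
- A variance-stabilizing transform step used with count data is replaced
  by log2(x+1) applied on demand: downstream procedures only need a
  monotone variance-damping transform, and log2(x+1) keeps the package
  free of count-model machinery.
- Derivation can legitimately return an empty signature (a dataset with
  zero enriched sets empties its cell type's intersection); this warns
  rather than raises.
- The planted-recovery checks summarize 50 simulations with 200
  permutations per enrichment run; these sizes hold the Monte-Carlo
  error of the medians well below the pass margins while keeping the
  default suite quick.
- The package derives signatures by rule; it does not ship a hard-coded
  published gene list, and reproducing any particular published list
  requires the original datasets.
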