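# cocusig

Tumor–stroma crosstalk gene signatures from co-culture transcriptomes.

When cancer cells and cancer-associated fibroblasts (CAFs) are grown in
direct co-culture, both cell types switch on a shared transcriptional
program (MAPK/AP-1–driven in squamous cell carcinoma models). Gene
signatures built from that program capture *active* cancer-cell–CAF
crosstalk rather than mere fibroblast abundance, and stratify patient
survival in bulk tumor cohorts. `cocusig` implements that analysis as a
tested, reusable pipeline for computational biologists:

1. **Signature derivation** from paired mono-/co-culture expression of
   several cancer/CAF dataset pairs, by two routes:
   - *pathway-frequency*: rank genes co vs mono by a Student t
     statistic, run gene-set enrichment (weighted Kolmogorov–Smirnov
     running sum, gene-set permutation null), pool leading-edge genes of
     sets enriched at FDR < 0.05, keep genes in ≥ 20% of the enriched
     sets, intersect across datasets per cell type, union cell types;
   - *fold-change*: keep genes with co/mono fold change ≥ 1.5 in every
     dataset of a cell type, union cell types.
2. **Contamination correction** of sorted co-culture samples: the
   contaminating fraction α is estimated by constrained least squares on
   lineage markers (CDH1/EPCAM/CD24/KRT\* vs COL1A1/COL1A2/DCN/CD248/PDGFR\*)
   under the mixture model s = (1−α)·own + α·other, then inverted per gene.
3. **Cohort scoring and survival**: per-sample score = mean per-gene
   z-score of log2(x+1) expression over signature genes; quartile
   stratification (Q4 vs Q1), Kaplan–Meier curves, log-rank tests, Cox
   proportional-hazards regression (Efron ties), HR = exp(β̂) with 95%
   Wald CIs, plus Spearman correlation and two-group t tests against
   cell-abundance scores.
4. **Multi-region concordance**: regions labeled high/low by median
   split; a patient with ≥ 2 regions is concordant when all regions
   agree. The observed concordant count is compared with the chance
   expectation E = Σᵢ [qⁿⁱ + (1−q)ⁿⁱ] by a two-sided Fisher's exact test.
5. **Synthetic data generators** for every input: paired mono/co
   experiments with a planted co-upregulated program, convex-mixture
   contaminated sorts, proportional-hazards cohorts, and multi-region
   cohorts with controllable concordance — so the whole pipeline is
   testable without any download.

## Worked example

```python
from cocusig import (SimulationConfig, run_planted_recovery, SurvivalSimConfig,
                     simulate_survival_cohort, quartile_survival_analysis)

# three simulated cancer/CAF dataset pairs with a 30-gene planted program
cfg = SimulationConfig(seed=7)
reports = run_planted_recovery(cfg)
for route, rep in reports.items():
    print(f"{route:10s} signature: {len(rep.signature)} genes "
          f"(recall {rep.recall:.2f}, {rep.false_positives} false positives)")

# score-dependent hazard: top vs bottom quartile survival contrast
cohort = simulate_survival_cohort(SurvivalSimConfig(seed=7, n_patients=500,
                                                    censoring_rate=0.3))
fit, _ = quartile_survival_analysis(cohort, "score")
print(f"Q4 vs Q1: HR = {fit.hr:.2f} (95% CI {fit.ci95_low:.2f}-{fit.ci95_high:.2f}), "
      f"log-rank p = {fit.logrank_p:.2e}")
```

prints

```
frequency  signature: 30 genes (recall 1.00, 0 false positives)
foldchange signature: 30 genes (recall 1.00, 0 false positives)
Q4 vs Q1: HR = 5.52 (95% CI 3.87-7.89), log-rank p = 6.87e-25
```

Both derivation routes recover the full planted crosstalk program with
no spurious genes, and the simulated cohort — whose hazard rises with
the signature score (true per-unit HR 2) — shows the expected strong
top-vs-bottom-quartile survival separation.

A `cocusig` command-line tool exposes the same stages
(`convert`, `filter`, `simulate`, `gsea`, `derive`, `score`,
`purity-correct`, `survival`, `concordance`); run `cocusig --help`.

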