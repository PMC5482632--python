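# rbescreen

Rank-based cross-platform differential-expression screening and
relapse-biomarker evaluation, written for transcriptomics of acute
leukemias but applicable to any two-condition expression comparison with a
time-to-event follow-up.

## The problem and the approach

Absolute microarray (or other platform) intensities are not comparable
across platforms, which frustrates pooling public expression data for
biomarker discovery.  Within one sample, however, the *ordering* of genes
is meaningful.  `rbescreen` implements the rank-based screen built on that
observation, plus the downstream clinical evaluation of a candidate
transcript:

* **Percentile rank scores.**  Per sample, intensities are ranked and the
  rank k of N maps to score ⌈100·k/N⌉ ∈ {1, …, 100} (ties averaged).  The
  **average rank score** of gene g in condition c is
  ARS_g(c) = mean over samples of the rank score, and the screening
  statistic is **Δ_g = ARS_g(case) − ARS_g(control)**.  Genes with Δ > 45
  and ARS(case) > 80 pass the screen; multi-probe genes are represented by
  the probe with the maximal pooled-sample ARS, and rank-based expression
  (RBE) curves display the distribution of a gene's rank scores per
  condition.  Everything after ranking depends only on within-sample order,
  so the screen is exactly invariant to strictly increasing per-sample
  (platform) distortions.
* **Diagnostic cutoff.**  ROC analysis of case vs. control transcript
  levels: trapezoid AUC (= Mann–Whitney U/(n₁n₂), ties ½) with DeLong 95%
  CI, Youden-index cutoff argmax_c {sens(c) + spec(c) − 1}, over-expression
  rate above a cutoff, and median dichotomization (ties to "low").
* **Outcome analysis.**  Relapse-free survival by Kaplan–Meier with
  Greenwood/log-log bands and the log-rank test; cumulative incidence of
  relapse with death in remission as a competing risk via the
  Aalen–Johansen estimator, CIF(t) = Σ_{tᵢ≤t} S(tᵢ⁻)·d(tᵢ)/n(tᵢ), compared
  between groups with a Gray-type permutation test; Cox proportional
  hazards on the cause-specific hazard (Efron ties, Newton–Raphson) with
  sequential backward elimination of covariates with Wald P > 0.1; landmark
  estimates at 5 years (60 months).
* **qPCR quantification.**  The comparative-Ct method (2^−ΔΔCt against a
  normal-control calibrator), dilution-series standard curves with
  amplification efficiency E = 10^(−1/slope) − 1, and absolute copy-number
  ratios.
* **Synthetic data.**  Seeded generators for two-condition expression
  cohorts (log-normal intensities, spiked rank-shifted genes, multi-probe
  genes, strictly increasing per-sample platform distortions) and for
  remission cohorts (proportional-hazards relapse, competing
  death-in-remission, administrative censoring), so the whole chain is
  testable without any download.

The bundled `load_published_screen()` table carries the published top-20
summary (gene, ARS per condition, Δ, and the updated columns) used as
worked input for the screen arithmetic.  See `docs/methods.md` for the full
methodological account and `examples/` for one runnable script per
capability.

## Worked example

`examples/03_survival_competing_risks.py` simulates a 168-subject remission
cohort in which a binary biomarker multiplies the relapse hazard by 2.5 and
death in remission competes, then estimates everything per biomarker group:

```
event
relapse     77
censored    74
death       17
 low: 5-y RFS 42% [28, 55%], 5-y CIR 38% [26, 51%] (n=84)
high: 5-y RFS 10% [3, 23%], 5-y CIR 86% [74, 96%] (n=84)
log-rank (RFS): chi2 = 14.52, P = 0.0001
Gray-type test (CIR): P = 0.0005
```

The high-level group relapses far more (5-year cumulative incidence 86% vs
38%, Gray-type permutation P = 0.0005) and has correspondingly worse
relapse-free survival; the bracketed ranges are 95% confidence intervals
(Greenwood for RFS, bootstrap for CIR).  Likewise
`examples/01_rank_screen.py` recovers spiked genes from a distorted
2,000-gene two-platform cohort and verifies that all 20 genes of the
published table pass the Δ > 45, ARS > 80 screen, and
`examples/04_cox_backward_elimination.py` recovers generating hazard ratios
of 5.32 and 0.5 while eliminating pure-noise covariates.

## Command line

A thin CLI wraps the same functions:

```sh
rbescreen simulate --kind expression --out expr.tsv
rbescreen screen expr.tsv --out hits.tsv
rbescreen roc levels.csv --out roc.json
rbescreen surv cohort.csv --group-col group --covariate age35
rbescreen qpcr ct_table.csv
rbescreen run pipeline.yaml --outdir out/
```

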