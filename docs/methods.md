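# Methods

This note documents the statistical machinery implemented in `rbescreen`,
the choices made where several defensible options existed, and what the
synthetic-data generators do and do not emulate.

## Percentile rank scores, ARS and the delta statistic

Microarray intensities are not comparable across platforms, but the ordering
of genes within one array is.  Each sample (array) is therefore reduced to
percentile rank scores: intensities are ranked ascending and the ordinal rank
k of N maps to the score ceil(100·k/N) ∈ {1, …, 100}; tied intensities
receive the mean of their mapped scores, and missing entries stay missing
(ranks use the observed N).  The ceiling convention guarantees the
top-ranked value of any sample scores exactly 100 for every N, and the
bottom value scores ceil(100/N) ≥ 1.  Because only within-sample order
enters, the entire downstream chain is exactly invariant under any strictly
increasing per-sample transformation — the property that makes the screen
platform-robust, and which the tests assert as byte-identical output.

The **average rank score (ARS)** of a gene in a condition is the arithmetic
mean of its rank scores over that condition's samples (pairwise-complete; a
gene needs ≥ 2 non-missing samples per condition to be scored).  The
screening statistic is **delta = ARS_case − ARS_control**, bounded by ±99.
The default screen retains genes with delta > 45 and ARS_case > 80, both
strict inequalities, ranked by ARS_case descending with delta as tie-break
(the ordering used when such tables are published).

When a gene is measured by several probes, the single probe with the
maximal ARS pooled over *all* samples represents the gene.  Pooling over
both conditions (rather than one) makes the choice symmetric, so the same
probe stands for the gene on each side of the comparison; probe-id order
breaks exact ties deterministically.

**RBE curves** show, per condition, the proportion of samples at each
integer rank score 1–100 (fractional tie-averaged scores are rounded to the
nearest bin).  Raw proportions sum to 1; the displayed curve may additionally
be smoothed with a Gaussian kernel, default bandwidth 3 rank units — curves
of this kind are published smoothed without a stated method, and σ = 3 is
the smallest bandwidth that suppresses single-bin noise at typical sample
sizes (tens to hundreds of arrays) without merging modes 30 rank units
apart.

**Plasticity (GPL) score.**  The published plasticity measure comes from a
companion method whose formula is not reproducible from available text.  The
implementation therefore ships a documented stand-in — the width of the
central 80% of the gene's rank-score distribution (q90 − q10), with the
quantile span configurable — and treats it as a relative spread measure
only: 0 for a constant gene, larger for more plastic genes.  Values are not
comparable to published plasticity scores and are never asserted against
them.

## ROC, AUC and the Youden cutoff

A sample is called positive when its transcript level is ≥ the cutoff
(higher = more disease-like).  The ROC curve is evaluated at every observed
level; the trapezoid-rule AUC then equals the Mann–Whitney probability
U/(n₁n₂) with ties counted ½, which the tests verify by exhaustive pair
counting.  The AUC confidence interval uses DeLong's placement-value
variance (a Wald interval clipped to [0, 1]); the published CI this mirrors
was reported without a named method, and DeLong is the standard
distribution-free choice.  The Youden-optimal cutoff maximizes
J = sensitivity + specificity − 1; ties are resolved toward the smallest
cutoff for determinism.  Median dichotomization assigns values strictly
above the median to "high" and ties to "low", so n_low ≥ n_high — consistent
with an 88/80 split of 168 subjects.

## Survival analysis under competing risks

Subjects enter at first complete remission; time is in months; each record
carries exactly one of `relapse`, `death` (in remission) or `censored`.

* **RFS** is estimated by Kaplan–Meier (via lifelines) with the
  exponential-Greenwood (log-log) confidence band.  By default both relapse
  and death in remission count as RFS events; since published RFS
  definitions sometimes count relapse only, the event set is a parameter
  (`events=`).
* **CIR** uses the Aalen–Johansen estimator, implemented directly:
  CIF_cause(t) = Σ_{tᵢ ≤ t} S(tᵢ⁻)·d_cause(tᵢ)/n(tᵢ) with S the all-cause
  KM.  The implementation is deliberately jitter-free so the identity
  CIF_relapse + CIF_death + S = 1 holds to 1e-9 at every event time and the
  no-competing-cause reduction CIF = 1 − KM is exact.
* **Group comparison of CIR** uses a Gray-type score: at every relapse
  time, observed relapses per group are compared with expectation under the
  pooled subdistribution hazard, where subjects who died in remission remain
  in the risk set weighted by the pooled censoring Kaplan–Meier
  G(t⁻)/G(tᵢ) (IPCW, as in the Fine–Gray construction).  The p-value is a
  seeded permutation p (default 1,000 label permutations), exact under the
  exchangeable null of equal cumulative incidence *and* equal censoring
  across groups; it reduces to the log-rank comparison when no competing
  events exist.  The permutation route avoids the closed-form variance of
  the asymptotic test and is calibrated by simulation in the test suite.
  Its limitation: under strongly group-dependent censoring the exchangeable
  null is misspecified.
* **Cox regression** models the cause-specific hazard: competing deaths are
  censored at their time (the subdistribution/Fine–Gray regression is out of
  scope).  The partial likelihood uses the Efron tie correction by default
  (Breslow available; the two coincide to 1e-9 without ties), maximized by
  Newton–Raphson with step halving, tolerance 1e-9 on the coefficient
  update, at most 50 iterations.  Covariates are centered internally for
  conditioning (the estimate is unaffected).  Constant covariates raise an
  error naming the covariate; a singular information matrix or |β| > 30
  raises a convergence error (monotone likelihood / perfect separation is
  never reported silently).  Wald CIs and p-values come from the inverse
  observed information; fits agree with an independent implementation to
  ~1e-5 in the tests.
* **Backward elimination** refits repeatedly, removing the single covariate
  with the largest Wald p among those with p > 0.1 (configurable
  `keep_alpha`), until all remaining covariates have p ≤ 0.1; the removal
  trace is returned.  Note the selection effect: with two pure-noise
  covariates the model empties in ~70% of replicates, not 0.9², because the
  covariate surviving the first round is the one with the smaller p.
* **Landmark estimates** (default t = 60 months, i.e. 5 years) read the
  step function at t; KM landmarks carry the Greenwood band, CIF landmarks
  use a seeded percentile bootstrap over subjects (default 500 resamples).
  A landmark beyond the last observed time carries the last value forward
  with a warning.

## qPCR quantification

Relative expression uses the comparative-Ct method: duplicate wells are
averaged at the Ct level, ΔCt = Ct_target − Ct_reference per sample, ΔΔCt is
taken against the mean ΔCt of the calibrator samples (normal controls), and
the relative level is 2^−ΔΔCt.  The method is invariant to any global Ct
shift applied to target and reference alike.  Standard curves are
least-squares fits of Ct against log10 quantity over a dilution series (≥ 3
points, negative slope required); the amplification efficiency is
E = 10^(−1/slope) − 1, equal to 1 for perfect per-cycle doubling
(slope −3.3219) and ≈ 0.93 at slope −3.50.  Absolute levels interpolate
copies from the curve and report target copies as a percentage of the
reference gene's copies.

## Synthetic-data generators

**Expression.**  Gene-wise log-normal intensities: each gene draws a mean
log-intensity once from N(6, 1); each probe of a gene adds a fixed N(0,
0.25) offset; per-sample noise is N(0, noise_sd) on the log scale (default
noise_sd = 1).  Effect genes are shifted upward in cases by `shift ×
noise_sd` log units and start just below the population median
(control-side mean rank score ≈ 43), emulating a moderately expressed gene
that becomes highly expressed in disease — the configuration under which a
rank shift is visible rather than clipped at the top of the scale.
Platform distortions are per-sample strictly increasing affine-plus-power
maps f(x) = a·x^p + b with a, p > 0, b ≥ 0 (drawn log-uniformly/uniformly
under `distortions="random"`); user-supplied callables are spot-checked for
monotonicity and rejected otherwise.  Defaults mirror the scale of the
emulated comparison: 690 case and 400 control arrays over 20,000 genes.

Deliberately *not* emulated: between-gene correlation (genes are
independent given their means; real co-expression modules would inflate the
variance of cross-gene summaries), probe-specific affinity biases beyond a
fixed offset, batch structure within a platform, and heavy-tailed outlier
arrays.  Passing tests therefore demonstrate correctness of the rank
machinery and its platform invariance, not robustness to correlated noise.

**Clinical cohorts.**  Covariates are binary (given prevalence) or normal.
Relapse times are exponential with hazard λ_r·exp(βᵀx) (proportional
hazards by construction); death in remission is an independent exponential
competing cause; censoring is administrative, uniform on (0, window].
Defaults: n = 168 subjects, λ_r = 0.012/month, λ_d = 0.003/month, window =
90 months — giving ≈ 47% cumulative incidence of relapse at 60 months (the
closed form λ_r/(λ_r+λ_d)·(1−e^−(λ_r+λ_d)t) is used as an oracle in tests),
between the arm-specific 5-year CIR values of the emulated cohort, with
follow-up spanning its 1–90-month range.  Not emulated: time-varying
hazards, covariate-dependent censoring, cohort structure such as cytogenetic
subgroups or treatment assignment mechanisms.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted tolerances: the platform-invariance check
uses a 2,000-gene, 50+50-sample cohort; hazard-ratio recovery and CI
coverage use 200 cohorts of n = 1,000 at the generating HR 5.32 (a
published multivariate HR reused purely as a simulation parameter);
backward elimination uses 200 replicates of the same size; log-rank
calibration uses 1,000 null cohorts of n = 100; the competing-risks
identities use 100 cohorts of n = 120.  Published patient-level results
(AUC 0.980, the 1.83% cutoff, arm-specific CIR/RFS percentages, the
multivariate hazard ratios) are *not* reproducible from summary data and
are never asserted as outputs; they enter only as generator parameters or
worked arithmetic on printed summary columns.

## Known limitations

* The plasticity score is a stand-in, not the published formula.
* Gray-type inference is permutation-based; no asymptotic variance is
  reported, and heavy group-dependent censoring violates its null.
* The Cox module has no time-dependent covariates, frailties, stratified
  baselines or Fine–Gray subdistribution regression.
* DeLong's Wald CI can degenerate at AUC = 1 (clipped rather than
  logit-transformed).
* `read_expression` loads the full matrix into memory; the format is
  tab-delimited text, not binary array containers.
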