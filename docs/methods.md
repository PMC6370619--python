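# Methods

This note documents the models the package implements, the assumptions
behind the synthetic-data generator, and the numerical and design choices
that were genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The scientific setting

Severely lymphopenic HIV patients (<200 CD4+ T cells/μL) starting ART are
followed at months {0, 2, 6, 12, 16, 20, 24, 28, 32, 36, 42, 48, 54, 60}.
Two recovery phenotypes are defined *empirically* from the CD4 trajectories
over the first 36 months: adequate responders (AIR), all of whom exceed
500 cells/μL at least once, and poor responders (PIR), who never do. The
package's four analysis stages — trajectory clustering, kinetic modelling,
group comparison, early prediction — mirror that study design.

## Exponential recovery model

CD4 count and CD4/CD8 ratio follow

    X(t) = A + B · (1 − exp(−t/τ))

with `A` the level at ART start, `B` the maximum attainable increase
(`A + B` the long-run asymptote) and `τ` the timescale in months. Group
structure: for CD4 counts, A is shared while B and τ are group-specific and
patients carry random effects on {A, B}; for the ratio, A and τ are shared,
B is group-specific, and random effects act on {A, B, τ}.

**Estimation.** Conditional on τ the mean is linear in (A, B), so the fit
profiles: the free parameters are the τ's and the Cholesky factor of the
random-effect covariance scaled by the residual variance (Ψ* = Ψ/σ²);
for each candidate the fixed effects are generalized-least-squares
solutions, σ² has a closed form, and the exact Gaussian marginal
log-likelihood is evaluated patient by patient (patients sharing a visit
pattern are batched). Nelder-Mead maximizes the profile, started from a
coarse τ grid {6, 12, 18, 30} with a two-stage heuristic (A₀ = mean
baseline, B₀ = mean last-minus-first per group). A random effect on τ is
handled by first-order linearization of the mean about τᵢ = τ; the
linearization point uses the current B estimates and is refreshed over as
many as three outer passes. Convergence is flagged at relative tolerance
1e−6 (iteration cap 200 per parameter); the best-so-far objective trace is
retained and is non-increasing by construction.

**Detection floor.** Counts cannot fall below the assay floor
(1 cell/μL). `fit_nlme(..., censor_at=1.0)` treats observations at or below
the floor as left-censored: after an initial fit they are replaced by their
conditional means under the fitted patient-level model (truncated-normal
expectation) and the model is refit, twice, warm-started. Without this
correction a hard floor biases A upward and B and τ downward in the low
group.

## Synthetic cohorts

No patient-level data are public, so all pipeline-level testing runs on
simulated cohorts. The generator's defaults are the study conditions:

- Groups of 14 (AIR-like) and 19 (PIR-like); 14-visit schedule above.
- CD4 kinetics per group from the published fixed effects
  (A = 130.1; B = 499.0/284.5; τ = 17.6/31.9 months), ratio kinetics
  (A = 0.163; B = 0.644/0.475; τ = 27.62).
- Patient-level Gaussian random effects on A and B (SD 60 and
  120 cells/μL; 0.05 and 0.10 for the ratio) and i.i.d. Gaussian
  measurement noise (SD 50 cells/μL; 0.05 for the ratio); counts floored at
  1 cell/μL, the ratio at 0.001. CD8 = CD4/ratio, so the three analytes are
  consistent. No generative model is published; these SDs are stand-ins,
  not estimates.
- Baseline covariates per group from the published summaries: age normal
  (38.1 ± 8.6 vs 45.3 ± 10.8 years, truncated to [18, 90]); log₁₀ viral
  load normal with the group medians as means and SDs chosen so the printed
  min-max ranges span roughly ±2.5 SD (0.35 / 0.41); sex, HCV and clinical
  category multinomial with the printed proportions.
- RTE% among CD4+ T cells rises logistically in time (midpoint 12 months,
  scale 6) from ~8% toward 30% (AIR-like) or ~6% toward 18% (PIR-like),
  observation noise SD 2 — the qualitative pattern of a thymic-function
  difference present from early therapy. Thymic volume change over the
  first year uses the published group means and SDs (+6.47 ± 4.59 vs
  +1.43 ± 4.89 cm³); thymic index is ordinal 1–3; sj-TREC frequencies are
  log-normal with an AIR-ward shift.
- Missingness: independent Bernoulli per non-baseline visit, default 0.05
  (the study's model sample sizes of 28–31 of 33 imply occasional missing
  values but state no mechanism).

What the generator does **not** emulate: viral-load decay, treatment-regimen
effects, within-patient autocorrelated measurement error, informative
missingness, or any real flow-cytometry structure. Passing tests on these
cohorts therefore demonstrate the *procedures* behave as specified, not
that the biological effect sizes of the original cohort are recoverable.

## Trajectory clustering

Step 1 computes the canonical 24 trajectory summary measures (range; mean;
SD; CV; change; change per unit time; change relative to first and to the
mean; linear-fit slope and R²; first-difference summaries and their ratios
to the mean and slope; second-difference summaries and ratios). First
differences are raw successive differences; the "per unit time" variant
divides by the time gap. Measures with zero denominators (e.g. slope ratios
of a flat trajectory) are flagged undefined, and imputed with the cohort
median before factor analysis, with a logged warning.

Step 2 standardizes the measures and runs a PCA on their correlation
matrix, retaining factors with eigenvalue > 1 and selecting for each the
measure with the largest absolute loading (ties and repeats resolved by the
canonical measure order; no rotation). Step 3 clusters the standardized
selected measures with k-means (k = 2, 50 seeded restarts, best
within-cluster sum of squares); rows are sorted by patient id first so the
partition is invariant to input order.

One robustness choice: before PCA and k-means, each measure is winsorized
at the extreme-outlier fences `P25 − 3·IQR` / `P75 + 3·IQR`
(linear-interpolation quartiles — the same rule the comparison stage uses
for outlier sensitivity). The ratio-type measures are heavy-tailed on noisy
trajectories, and without capping a single aberrant trajectory can claim a
k-means cluster of its own.

Labelling is a posteriori: the cluster with the larger fraction of patients
whose CD4 maximum over months 0–36 *strictly* exceeds 500 cells/μL is AIR;
an exact tie falls back to the higher cluster-mean CD4 with a warning.

A calibration fact worth knowing: with the default random-effect SDs the
two latent groups genuinely overlap (the B difference of 214.5 cells/μL is
1.8 SD), so even a supervised classifier cannot separate them perfectly;
unsupervised recovery of the latent labels on default-noise cohorts is
partial by construction. The well-separated regime (small SDs) recovers the
labels exactly (see the clustering tests).

## Comparison statistics

- Routing: Shapiro-Wilk at α = 0.05 on each sample; both normal → pooled-
  variance Student's t (df = n₁ + n₂ − 2) with Cohen's d on the pooled SD;
  otherwise Mann-Whitney U with r = Z/√N (tie-corrected normal Z, signed
  positive when the first sample tends larger; exact p for small tie-free
  samples). Paired designs use |mean Δ| / SD(Δ).
- Fisher's exact test for 2×2 tables with the cross-product odds ratio
  (a·d)/(b·c) exactly as the table is passed — note the OR flips to its
  reciprocal if the rows are swapped, so the row convention must travel
  with the table. Cramér's V = √(χ²/(n·(min(r,c)−1))) for larger tables.
- Magnitude bins as published: d < 0.3 small, [0.3, 0.8) medium, ≥ 0.8
  large; r at 0.3/0.5; V at 0.3/0.7; correlations at 0.3/0.5/0.7/0.9
  (negligible/low/moderate/high/very high). The printed d bins overlap at
  0.8; the upper bin wins.
- Bonferroni threshold α/m exactly; flags are p < α/m.
- Extreme outliers: outside [P25 − 3·IQR, P75 + 3·IQR]; every comparison
  can be re-run with them removed (per sample) and the significance
  agreement reported.
- Derived features: interval CD4 slopes by OLS on all visits in the closed
  interval; thymic score = mean(volume) × mean(index) over the first year;
  RTE absolute counts, naive/memory ratio, TREC/mL (assumed
  1.5·10⁶ PBMC/mL — the conversion concentration is not published) and the
  sj/β TREC ratio with the six DJβ1 frequencies *summed* in the
  denominator. Zero denominators yield flagged undefined values.

## Prediction

Outcome coding Y = 1 for AIR. Candidates measured between baseline and
month 6 are screened univariably (retain Wald p < 0.20; a
likelihood-ratio variant is a flag); backward stepwise removes the largest
Wald p ≥ 0.05 until all coefficients are significant or one predictor
remains, recording the trace. Final-model checks: LRT against the full
model (χ², df = parameter difference), Hosmer-Lemeshow over deciles of risk
(χ²(g−2), ties kept together), trapezoidal AUC (identical to the
Mann-Whitney pair-win probability) with bins poor/fair/good/excellent at
0.7/0.8/0.9. Classification: "probably PIR" iff P(PIR) ≥ 0.5; sensitivity
is the percentage "probably PIR" among PIR, specificity the percentage
"probably AIR" among AIR. AIC comparisons refuse models fitted on different
rows — subset to shared complete cases first.

The four published coefficient sets are shipped as a versioned JSON
resource and evaluated as P(PIR) = 1/(1 + exp(a + b·x₁ + c·x₂ + d·x₃)) in
the study's units (years, log₁₀ copies/mL, cells/μL, %). The "% RTE ratio
(0/6 mo)" predictor is computed as baseline ÷ 6-month value; the label does
not fix the direction, so the choice is recorded here.

## Pipeline

`run_pipeline` chains simulate/load → validate → cluster → kinetics (CD4
and ratio) → compare (at a configurable visit, Bonferroni m = 14 by
default) → predict (screen → stepwise → evaluation, plus the published
models) → report. Every randomized stage consumes a sub-seed derived from
the master seed and the stage name (CRC32), and the JSON report echoes the
sub-seeds and every convention (OR type, quartile rule, thresholds), so a
report is reproducible byte-for-byte and self-describing. Failures halt
with the stage name.

## Problem sizes used in the automated checks

The simulation-based checks use 200-patient cohorts (50 replicates) for
kinetic parameter recovery, 100 study-sized replicates for cluster
recovery, and exhaustive enumeration up to n = 12 for the exact-test
oracles; these sizes make the whole suite run in minutes on one CPU while
keeping Monte-Carlo error small relative to the asserted margins.

## Known limitations

- The NLME fitter's τ-random-effect handling is a first-order
  linearization, adequate for moderate τ heterogeneity only.
- The cluster-label step assumes exactly two clusters; model-based curve
  clustering is out of scope.
- The published-model coefficients are transcribed constants; their
  standard errors are not published, so no uncertainty is propagated.
- Generator covariate distributions are location/spread emulations of
  printed summaries; joint dependence between covariates (beyond group
  membership) is not modelled.
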