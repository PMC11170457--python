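# Methods

This note documents the models, conventions and numerical choices behind
`actijive`, and what the synthetic generators do and do not emulate.

## Day grid, wear and inclusion

Analysis days run **noon to noon**, so a night's sleep is never split
across days and a post-midnight onset (e.g. 00:40) stays continuous with a
pre-midnight one (23:40) on the 12–36 h axis.  A day is *valid* when the
recording covers the full 1440 minutes and wear time strictly exceeds
16 h (960 minutes); subjects need at least 7 valid days (configurable).
Wear detection itself is out of scope: wear is an input column (or assumed
true), matching the usual division of labour with device software.
Non-wear minutes are excluded from every feature numerator and
denominator; they are not imputed.

## Sleep features

Detection is a count-based heuristic operating on one day grid at a time:

1. running-median smoothing of counts (`smooth_width` = 11 min);
2. rest flag = smoothed count < `theta_sleep` (10 counts/min) and worn;
3. a majority filter (`block_width` = 61 min) marks rest-dominated
   stretches; the sleep period is the longest such stretch of at least
   `min_period` = 180 min, trimmed to its first and last raw sub-threshold
   minute (so the period begins and ends with a sleep minute);
4. within the period, the minute-level sleep flag is simply
   `count < theta_sleep`.

Nights without a qualifying stretch are missing and are excluded from the
per-subject averages.  Precomputed per-night annotations (GGIR-style
summary CSV) can replace detection entirely.

Per night: Duration = sleep minutes / 60 (time *asleep*, not the period
length); Efficiency = sleep minutes / period minutes; NWB = number of wake
runs of ≥ 5 minutes inside the period; NSB = number of maximal runs of
sleep minutes (a config switch instead splits blocks only at ≥ 5-minute
wake runs).  Onset/Wakeup/Midpoint are averaged on the continuous
noon-to-noon axis and reported mod 24.  The definitions Duration <
(Wakeup − Onset) with Efficiency = Duration/(Wakeup − Onset) are forced by
the published cohort's internal arithmetic (mean Duration 6.69 h vs mean
period ≈ 7.7 h at efficiency 0.87).

## Physical-activity features

TAC = Σ counts and TLAC = Σ log(1+count) over worn minutes.  Intensity
classes use per-minute count thresholds `theta_sed` = 50 and `theta_mvpa`
= 1000 (device- and scale-dependent; configurable): sedentary < 50 ≤ light
< 1000 ≤ MVPA.  TST spans the full 24-h day — sleep minutes are sedentary
— which is what makes TST + LiPA + MVPA = 1440 on a fully worn day.

Fragmentation: SATP = (# sedentary→active transitions) / (# sedentary
minutes) and symmetrically ASTP.  Transitions are only counted between
time-adjacent worn minutes; the last minute of a day contributes to the
denominator but has no outgoing transition.  By default fragmentation is
computed over the whole day (consistent with the 24-h TST convention); a
`fragmentation_wake_only` switch restricts it to minutes outside the
detected sleep period, which is the estimand that matches a wake-time
bout process (the end-to-end recovery experiments use this switch, since
the generator's Markov chain governs wake time only — including the sleep
period would dilute SATP by a factor of roughly (wake sedentary
minutes)/(all sedentary minutes) ≈ 0.6).

## Circadian features

* **Cosinor**: least squares for `x(t) = M + b_c cos(ωt) + b_s sin(ωt)`,
  ω = 2π/24 h⁻¹, on all worn minutes of valid days.  Amp = √(b_c²+b_s²);
  the acrophase is reported in negative radians, Acro = −2π t_peak/24 ∈
  (−2π, 0], so a 2 PM peak gives ≈ −3.67.  Constant input yields Amp 0 and
  a missing acrophase.
* **IV / IS** on hourly bins (hours with ≥ 30 worn minutes):
  IV = N·Σ(Δx)²/((N−1)·Σ(x−x̄)²), IS = N·Σ_h(x̄_h−x̄)²/(24·Σ(x−x̄)²).
  Useful limits (used as test oracles): a pure 24-h sinusoid gives
  IV → 2(1−cos(2π/24)) ≈ 0.0681; i.i.d. noise gives IV ≈ 2 and
  IS ≈ 1/days; an exactly repeating daily pattern gives IS = 1.
* **L5 / M10**: extrema of wrap-around 300-/600-minute window means of the
  average diurnal (clock-time) count profile; times are window-midpoint
  clock hours, ties resolve to the earliest window start.  Reported times
  are absolute clock hours (the published table's small signed values use
  an unstated reference point; a cohort-centred variant is emitted
  alongside in the feature CSV, and after the pipeline's z-scoring the two
  are identical anyway).  L5Time sits near 2–3 AM for typical subjects;
  a subject whose least-active window midpoint crosses midnight would wrap
  (0.1 vs 23.9) — a known limitation of the absolute-hours convention.
* **fPCA**: the per-subject mean log(1+count) profile on the 1440-minute
  clock grid is circularly smoothed (moving average, width 21), profiles
  are column-centred across subjects, and the top-4 right singular vectors
  give the component curves; subject scores are the projections.  Sign
  rule for determinism: each component's loading curve must have positive
  integral over 10:00–14:00.  This is a standard discretised fPCA; no
  spline penalty is applied, so component curves are only as smooth as the
  moving average makes them.

## JIVE

Preprocessing: per-column median imputation, z-scoring (SD with ddof 1),
then each block is divided by its Frobenius norm so the three blocks
contribute equal total energy to the joint step.  A zero-variance column
is an error naming the feature.

Estimation alternates (initialising the individual parts at zero):

* joint step — best rank-r SVD approximation of the column-concatenation
  of (X_k − A_k); the joint subject basis U is the orthonormalised score
  matrix;
* individual step — best rank-r_k approximation of (I − UU')(X_k − J_k),
  which enforces U'U_k = 0 exactly;

until ‖ΔJ‖_F < 1e-8 (absolute; the blocks have unit norm).  Each step is
the exact minimiser of the total residual sum of squares given the other
part, so the objective is non-increasing; on pure-noise inputs the plateau
can be long, hence the generous default `max_iter` = 2000 (fits of this
size cost ~0.1 ms/iteration).  At the fixed point the decomposition is
orthogonal, giving the per-block energy identity ‖X‖² = ‖J‖² + ‖A‖² +
‖residual‖² to the convergence tolerance — the variance-explained
fractions reported per block.

SVD sign indeterminacy is resolved by forcing the largest-magnitude
element of every loading column positive.  Loading columns have unit norm
(joint components across the concatenated 28 features, individual
components within their block), so squared loadings sum to one and read as
proportional feature importance; the loading table flags features above
5% of a component's variation.

Scores extracted for regression are standardized to mean 0 / SD 1.  On
column-centred inputs all scores are exactly mean 0, so standardization is
a pure rescale and preserves the orthogonality joint-vs-joint and
joint-vs-individual.  Individual scores of *different* blocks are not
constrained; their empirical correlations are small but nonzero and are
not asserted to vanish.

**Rank selection** is permutation-based: the observed singular values of
the concatenated (X_k − A_k) are compared with the (1−α) quantile (α =
0.05, 99 permutations) of the largest singular value after independently
permuting each block's rows; individual ranks are tested analogously
within each block after removing the fitted joint part, with the null
built by permuting each column's entries.  Selection and fitting iterate
until the ranks are stable (at most 10 cycles).  Two documented
properties of this scheme: (i) row permutation preserves each block's
*within-block* spectrum, so a joint component much weaker than the
strongest within-block structure can fall below the null threshold —
equal-strength planted components are selected reliably (the acceptance
experiment plants equal weights for this reason), strongly skewed ones are
not guaranteed; (ii) with α = 0.05 per test and four tests (joint + three
blocks), pure-noise inputs select *all* ranks zero in only ≈ 80% of runs,
although each individual test is calibrated at its nominal level.

## Association models

Descriptive tables use the chi-square test of independence (no continuity
correction) for categorical rows and one-way ANOVA for continuous rows,
with group-denominator percentages and mean (SD) per group.  Pooling
helpers recombine per-group counts and means into whole-cohort summaries
(size-weighted means), which is also how the published cohort-level
figures are recomputed from its printed group table.

Each MDD contrast is a **separate** maximum-likelihood logistic fit of
case (lifetime = current ∪ remitted, or current, or remitted) versus the
no-MDD group, on all nine standardized JIVE scores simultaneously plus
covariates (age, sex, BMI, current anxiety, current SUD; medication
optional).  Wald 95% CIs and p-values are reported.  Newton iteration
falls back to BFGS when the Hessian is singular (e.g. a binary covariate
with a handful of positives); separation and non-convergence are flagged
on the result, never silently dropped.  Headline p-values are not
adjusted for multiple comparisons; a Benjamini–Hochberg column is emitted
alongside for transparency.

## Synthetic cohorts

### Feature tier

`X_k = U C_k W_k' + U_k D_k V_k' + E_k` with i.i.d. standard-normal joint
(U, shared) and individual (U_k) factors.  Component scales are solved so
the expected block energy split equals the planned
joint/individual/residual fractions (defaults: the reference partition
58.5/34.4/7.1 for SL, 79.5/17.6/2.9 for PA, 54.5/25.5/20.0 for CR, with
joint component strengths split 0.5/0.3/0.2 so component order is
identifiable).  Loading frames are *balanced* — alternating
row-flattening with polar re-orthonormalisation — and per-column noise
tops every feature up to a common total variance.  This matters because
the pipeline z-scores columns: with random frames the planted columns
have unequal variance and z-scoring would tilt the realized energy split
by up to ~0.08; with balanced frames the planned partition survives the
pipeline's own preprocessing.

The binary outcome follows a logistic model on the standardized planted
factors with per-SD log odds ratios taken from the reference lifetime
associations (0.86 on Joint-1, etc.); the intercept is solved by bisection
so the marginal prevalence matches the reference (49.76% lifetime, of
which 16% current).  Covariates are drawn near the reference marginals
and are independent of the latents (confounded designs are constructed
ad hoc in tests).  Feature columns are affinely mapped onto the reference
means/SDs so tables look realistic; the map is invertible and does not
affect any z-scored analysis.

### Epoch tier

Per subject: a cosinor envelope λ(t) = M + A cos(ω(t − t_peak)) with
M ~ N(29.57, 9.48) clipped at 5, A = M · ratio with ratio ~ N(0.83, 0.06)
(drawing the amplitude as a ratio keeps the relative amplitude near the
realistic 0.8 band), acrophase ~ N(−3.65, 0.32); sleep onset ~ N(23.5,
1.0) and wakeup ~ N(31.25, 0.9) across subjects with 0.3 h nightly
jitter; wake-time two-state Markov dynamics with p(S→A) ~ N(0.07, 0.015)
and p(A→S) ~ N(0.25, 0.04), simulated by geometric run lengths from the
stationary law.

Count laws are built so that the *expected* count at every minute equals
the envelope, which keeps the cosinor identifiable:

* sleep minutes: a clustered burst mixture — near-still baseline
  (exponential, mean 2) plus movement-burst runs (two-state process,
  enter 0.055/min, exit 0.5/min) whose mean is solved so the stationary
  mixture mean equals λ(t).  Burst clustering keeps the number of sleep
  blocks realistic and the minute-level efficiency near 0.87–0.90;
* planted wake bouts (Poisson 1.5/night, ≥ 5 min) with gamma counts (mean
  30) provide detectable NWB events;
* wake minutes: sedentary minutes draw Uniform(10, ~30) — above the sleep
  threshold (so evenings do not look like sleep) and below the sedentary
  threshold — while active minutes draw a shifted gamma above the
  sedentary threshold, with mean set so the sedentary/active mixture at
  the stationary active fraction equals λ(t).  A small vigorous tail
  (4% of active minutes with headroom, mean 1200 counts, mean-compensated)
  keeps the MVPA feature non-degenerate.

Near the sleep edges the class floors (sedentary ≥ 10, active > 50) make
the smallest achievable wake mean ≈ 19 counts/min, above the envelope for
low-mesor subjects in the late evening.  Left alone this biases the
recovered acrophase late by ≈ 0.05 rad at the cohort level.  The
generator therefore applies a *cosinor-orthogonalising correction*: per
subject, the expected excess over the envelope is projected onto the two
24-h harmonics and removed from the midday active mean
(headroom-weighted, so minutes near the floor move little); for deeply
floored subjects only a partial correction is feasible.  The residual
cohort-level acrophase bias is ≈ −0.02 rad, well inside the Monte-Carlo
band of the 200-subject acceptance experiment.

What the generator does **not** emulate: real inter-minute count
autocorrelation within states, naps and split nights, seasonal or
weekday structure, device noise, or the published cohort's exact NSB
scale (the burst process yields ~20–25 blocks/night vs 14 published; the
published table's TLAC/MVPA magnitudes are internally inconsistent with
its TAC/Mesor scale under any single count threshold, so the generator is
calibrated to the TAC/Mesor/L5/M10 scale and MVPA is small).  Passing the
recovery experiments therefore demonstrates correctness of the estimators
under the stated model, not fidelity to every marginal of real wrist
actigraphy.

## Acceptance experiments

`scripts/acceptance.py` (seeded, self-contained) recomputes: the pooled
demographic summaries from the published group table; noiseless JIVE
exact recovery (residual < 1e-10) and rank-selection recovery over 20
seeds (equal-strength planted components, n = 200); the energy identity
over 100 random instances; closed-form oracles (IV of a sinusoid, cosinor
on a noise-free cosine); the default feature cohort's variance partition
and selected ranks at n = 2317; epoch-tier recovery of onset, acrophase,
SATP/ASTP and TAC at 200 subjects × 14 days; the mean recovered per-SD OR
(target 0.86) with CI coverage over 100 replicates at n = 2317; and the
per-predictor type-I error over 1000 null replicates at n = 500.  The
regression experiments regress on the *planted* standardized factors:
estimated components equal the planted ones only up to rotation within
nearly-equal singular values and a sign convention, so per-coefficient
recovery is well-posed against the planted scores (component
identification is checked separately via score correlations).  Problem
sizes were chosen to keep the whole script under a minute on one CPU
while leaving Monte-Carlo error well below the tolerances tested.
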