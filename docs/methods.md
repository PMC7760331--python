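# Methods

This note documents the models, defaults and numerical choices behind
`pupilarousal`, and what the synthetic cohorts do and do not emulate.

## Task and signal model (synthetic cohorts)

Each simulated subject performs an interleaved sequence of cued anticipation
trials, 10 per condition (reward, neutral, no-response control), pseudo-randomly
ordered. A trial holds a 1 s pre-cue baseline plus a 6 s anticipation window
sampled at 250 Hz (`round(duration × rate) + 1` samples). The noiseless pupil
signal is flat during the baseline and ramps linearly during anticipation;
population mean slopes are +0.12 (reward), +0.07 (neutral) and −0.07
(control) units/s, so reward > neutral > 0 > control — dilation while a
response is prepared, constriction under the no-response cue. A subject's
slopes are shifted by a latent arousal trait (SD 0.055 units/s on the reward
slope, with loadings 0.6 and 0.2 on neutral and control); the trait is the
single factor tying pupil behavior to clinical scores and response times.
The baseline exists so onset alignment and run-level normalization are
exercised; inter-trial intervals are not modeled (the source task leaves
them unspecified, so trials abut).

Measurement noise is stationary AR(1) at the sample level (SD 0.3 units,
lag-1 coefficient 0.995, i.e. ~0.8 s correlation time). Pupil noise is
strongly autocorrelated in real recordings; white noise would make
derivative-based scores unrealistically stable. With these values the
split-half reliability of the 5-trial dilation half-means is ≈ 0.75–0.8,
matching the "high (>0.7)" split-half correlations such tasks show.

Artifacts: blinks arrive as a Poisson process (15 events/min, duration
truncated-normal around 200 ms) and blank pupil samples; gaze excursions
(probability 0.05 per trial, one contiguous episode of 0.6–1.6 s, ±400 px)
displace the gaze trace. Both processes are independent, and a ground-truth
mask of altered samples is retained for bookkeeping tests. A run becomes a
run-QC failure with probability 0.075 (the observed dropout rate for
>15%-missing runs in comparable cohorts) by inflating its blink rate
five-fold. Response times are Gaussian around a subject-level center
(0.28 ± 0.05 s between subjects, 0.05 s within, clipped at 0.1 s); the
adaptive deadline is a fixed-step staircase (start 0.4 s, step 0.02 s,
shorten on success / lengthen on failure), whose equilibrium success rate
is 1/2 for any stationary RT distribution.

### Clinical scores and effect calibration

Symptom counts are integers 0–9. Controls draw from a small-count marginal
(P = 0.45/0.30/0.15/0.10 on 0–3; controls never exceed 3), the depressed
group from a Binomial(9, p) with p solved so that P(count ≥ 5) equals the
acute fraction 23/41. Symptom impact (0–10) and anhedonia (≥ 0) are noisy
transforms of the count, so their correlations with dilation are
realistically weaker than the count's. The acute flag is count ≥ 5.

The generator's contract is that the **measured** reward-dilation score
(after the full default preprocessing) correlates with symptom count at the
configured target in expectation. Two calibration steps make that hold:

1. *Attenuation.* The measured score is the true slope attenuated by
   trial-level noise at the averaging-window endpoints **and** by the
   sampling noise of the per-run z-scoring divisor (the pooled run SD is
   itself a random quantity under slow AR(1) noise, and mildly
   trait-dependent). A closed form for the combined factor is impractical,
   so the generator measures it once per noise configuration: a fixed-seed
   internal simulation pushes 800 subjects with stratified traits through
   the full default pipeline and correlates measured scores with generating
   slopes (a ≈ 0.86 under defaults). The result is cached and independent
   of cohort size, seed and targets. The analogous RT factor (median of 10
   noisy RTs) uses the finite-sample variance of the normal median.
2. *Linkage.* The group-specific count marginals differ so strongly that a
   within-group Gaussian copula cannot reach a pooled correlation of −0.5:
   the between-group count variance dilutes it below the target for any
   copula strength. The arousal trait is therefore drawn conditionally
   Gaussian given the *standardized realized count* (pooled moments in
   closed form), trait = c·z_count + √(1−c²)·ε with c = target/a. This
   makes corr(trait, count) = c exactly, including the group-mixture
   component, at the cost that the within-depressed correlation is somewhat
   weaker than the pooled one. Response times attach to the trait the same
   way. Infeasible targets (|c| ≥ 1, or a non-PSD implied latent matrix)
   raise a configuration error.

Calibration assumes the default preprocessing parameters; analysing a
cohort with non-default QC settings will realize slightly different
effect sizes.

What the simulator does **not** emulate: luminance responses (cues are
isoluminant by design), saccade kinematics, pupil foreshortening, slow
vigilance drifts across the run, item-level clinical missingness, or any
neural (fMRI) layer. Passing tests therefore certify the statistical
machinery under the stated generative model, not robustness to every
property of real recordings.

## Preprocessing

Stages run strictly in this order per subject-run:

1. **Run QC** — missing fraction computed over all samples *before*
   interpolation; excluded iff strictly greater than 0.15.
2. **Blink interpolation** — straight line between nearest valid neighbors;
   leading/trailing gaps take the nearest valid value; an all-invalid trace
   is marked unusable and its trial discarded.
3. **Trial QC** — discard when gaze stays outside the fixation window for a
   contiguous episode strictly longer than 1 s (a cumulative-time variant is
   available by flag; "remained outside" reads as a sustained episode), or
   when strictly more than 50% of samples are interpolated. The window is a
   rectangle of configurable half-widths (default 150 px) centered on the
   subject's median gaze — the source pipeline gives no dimensions.
4. **z-transform** — one affine transform per run, pooled over all kept
   samples, after interpolation and before differentiation (both size and
   dilation are conventionally reported in z-units). Zero variance is an
   error, never a silent pass-through.
5. **Dilation** — first difference divided by the sampling interval, no
   smoothing; window averaging already suppresses sample noise.
6. **Summaries** — per-condition trial means of window-averaged size and
   dilation over the closed window [0 s, 6 s]; differential scores
   (reward−neutral, reward−control); median RT per response condition over
   successful *and* failed trials (RT is behavioral and independent of pupil
   QC). The window mean of the dilation series telescopes exactly to
   (endpoint − startpoint)/duration, which the tests assert to 1e−12.

All thresholds are strict inequalities ("more than"); boundary cases (15.0%
missing, exactly 1 s outside, exactly 50% interpolated) are kept.

## Bayes factors

The correlation test uses the exact sampling density of the Pearson
correlation under bivariate normality (hypergeometric closed form) rather
than a Fisher-z approximation — accurate at small n and directly
Monte-Carlo-checkable. The stretched beta prior of width w is Beta(1/w, 1/w)
mapped onto (−1, 1); width 1 is uniform. One-sided variants restrict and
renormalize the prior; with a symmetric prior the two one-sided BFs average
to the two-sided one (asserted in tests). BF₁₀ is an adaptive quadrature
over ρ with relative tolerance 1e−9 (an error above 1e−6 raises). Analyses
are computed from sufficient statistics (n, r); a vector interface wraps
them.

The two-sample test is the JZS default: effect size δ ~ Cauchy(0, 0.7)
(0.7 exactly, not 0.707), BF₁₀ = ∫ f_nct(t; ν, δ√n_eff) π(δ) dδ / f_t(t; ν)
with n_eff = n₁n₂/(n₁+n₂) — the t statistic is sufficient. Partial
correlations residualize x and y on the covariates plus intercept by least
squares and enter the correlation BF with effective n reduced by the number
of covariates; this is an approximation to the common software default,
which names no method. Evidence bands: (1, 3] anecdotal, (3, 10] moderate,
(10, 30] strong, (30, 100] very strong, > 100 extreme, mirrored
reciprocally for the null; exactly 1 is equivocal.

Both quadrature routes are cross-checked against independent Monte Carlo
marginal-likelihood estimators (prior sampling, 10⁶ draws in the acceptance
suite) within 3 MC standard errors.

## Latent correlation with known measurement error

Observed pairs are noisy readings of latent true scores (bivariate normal);
SEMs are fixed and known, SEM = SD·√(1 − reliability), identical across
subjects within a variable (one reliability per instrument). Priors: means
uniform on (−2, 2) and (0, 20), SDs uniform on (0, 2) and (0, 10), ρ
uniform on (−1, 1). Symptom counts are treated as continuous with Gaussian
error — fidelity to the established analysis, despite integer data.

Since every layer is Gaussian the latent scores are marginalized exactly
(observed covariance Σ + diag(SEM²)), leaving a 5-parameter posterior whose
likelihood depends only on (n, mean vector, scatter matrix) — evaluation is
O(1) in n. Sampling uses the affine-invariant ensemble sampler (emcee):
4 independent ensembles of 64 walkers, 600 warmup steps, 12,800 retained
draws per ensemble by default; split R-hat across ensembles and bulk ESS
come from arviz, with R-hat ≥ 1.01 flagging (never silently passing) a
non-converged result. Identical seeds give identical draws. A prior-only
mode replaces the likelihood with a constant and must reproduce every prior
(Kolmogorov–Smirnov distance < 0.05), which guards against sampler and
bounds bugs.

Directional hypotheses use the encompassing-prior interval Bayes factor:
posterior odds of {ρ < c} from the draws divided by the analytic prior odds
under the uniform prior ((c+1)/2 against the rest). When all posterior mass
falls on one side, the BF is reported as the bound resolvable with the
available draws and flagged. The attenuation diagnostic reports the naive
Pearson r, the classical disattenuated estimate r/√(rel_x·rel_y) and the
posterior mean ρ side by side; under error-free data all three agree.

The pipeline runs the model with both a high (0.94, two-day test–retest)
and a low (0.7 floor) pupil reliability, plus the cohort's own split-half
estimate when admissible, and reports the spread of posterior means — the
"similar results under either reliability" claim is checked qualitatively
(same sign, overlapping intervals), not numerically. The reliability for
the symptom instrument (0.78) is an agreement coefficient (kappa) pressed
into the Pearson-reliability role; that is the established analysis's own
conservative approximation and is inherited as such.

## Reliability

Split-half reliability correlates per-subject means of trials 1–5 against
6–10 (default; odd/even split available since drift biases a first/last
split), across subjects, dropping (and logging) subjects with an empty
half. The Spearman–Brown step-up 2r/(1+r) is reported alongside but never
substituted — the raw split correlation is the headline value. Negative
reliabilities are rejected at SEM conversion with guidance rather than
propagated into an imaginary SEM. Split-half estimates are computed per
condition, since whether the original estimate pooled conditions is
unspecified.

## Pipeline and group contrasts

The default analysis plan correlates reward-condition mean dilation with
symptom count, impact and anhedonia in the full sample and the
depressed-only sample (plain and age/sex-adjusted), adds the
dilation–median-RT correlations per response condition, and contrasts
depressed-vs-control and acute-subgroup(≥5 symptoms)-vs-control with JZS
t-tests on per-condition dilation and differential scores. Group
comparison by independent t-tests on these scores is a deliberate
simplification of a repeated-measures Bayesian ANOVA model comparison; it
answers per-measure questions, not the model-space question. Subjects
failing run QC are excluded from all analyses; item-level missingness is
handled by per-analysis listwise deletion, and every evidence row carries
the n actually used. Simulation is driven solely by the cohort seed, so
changing the analysis plan never changes the data; the MCMC stage derives
its seed from the cohort seed.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own verification design: calibration invariants use
2000-subject cohorts (sampling SD of a correlation ≈ 0.02); oracle
agreement uses 10⁶ Monte Carlo draws on 3×3 grids; measurement-error
recovery uses 100 replicates at n = 41 with 2 ensembles × 6,400 draws;
power checks use 100 replicates of the 41+25 design for the effect and 100
for the null; the attenuation check uses one n = 5000 cohort; the staircase
check uses 10,000 trials. Large simulated cohorts are generated and scored
one subject at a time (`iter_cohort` / `simulate_scored`) so memory stays
flat.

## Known limitations

* The attenuation calibration is empirical (cached internal simulation);
  its residual error (~±0.01 on a target of 0.5) is small against the
  ±0.05 calibration contract but not zero.
* At n = 41 with reliabilities (0.94, 0.78) the sampling SD of any
  disattenuated correlation estimate is ≈ 0.15; point estimates of ρ from
  single cohorts of that size are intrinsically that uncertain, and no
  estimator in this package (or elsewhere) can beat it. Interval coverage,
  not point accuracy, is the meaningful guarantee at that size.
* The within-depressed dilation–symptom correlation is structurally weaker
  than the pooled one under the single-factor linkage (see calibration);
  generating both at a common target would need a richer latent model.
* Ensemble-sampler walkers are not independent chains; R-hat across
  independent ensembles is the honest diagnostic and is what is computed.
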