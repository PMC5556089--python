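# Methods

This note documents the statistical model, the synthetic-data generator, and
the numerical choices behind `mlmed`, in the spirit of a package methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Two-level mediation model

The estimand is the group-level indirect effect of a binary cue contrast x
(±1 for the extreme price cues; a 3-level centred linear coding is available
as `x_coding="linear"`) on a rating y through a per-trial brain mediator m.
Per subject, three OLS regressions over trials give the path coefficients
(a, b, c, c′); wine identity and payment condition are included as covariates
of no interest in *all three* equations, which makes the decomposition
`c = c′ + a·b` an exact algebraic identity per subject (verified to 1e-10 in
the tests).  Middle-price trials are dropped entirely in the ±1 coding; trials
excluded by GLM QC are removed listwise from x, m and y.

At the second level, subjects are the only random unit.  The group indirect
effect is the unweighted subject mean of a·b, and with a population (1/n)
covariance it decomposes exactly as `mean(ab) = mean(a)·mean(b) + cov(a, b)`.
The covariance term matters: a region can mediate consistently at the
population level even when individual path coefficients are heterogeneous,
as long as subjects with strong cue→mediator coupling also show strong
mediator→rating coupling.  A sample-covariance (1/(n−1)) mode exists but is
off by default because it breaks the identity.

Degenerate subjects (mediator constant, or exactly collinear with the cue
and covariates, at a voxel) are dropped at that voxel only and counted in
the output; precision-weighted hierarchical summaries are out of scope.

## Bootstrap inference

Whole subject rows of the [a, b, c, c′, a·b] matrix are resampled with
replacement (default 10,000 resamples); each resample contributes the mean
of every column.  Because the covariance identity holds within every
resample, the resampled mean of the a·b column *is* the multilevel indirect
effect statistic.  Confidence intervals are percentile intervals and the
two-tailed p is `2·min(P(θ* ≤ 0), P(θ* ≥ 0))`, with exact zeros counted on
both sides, floored at 2/n_boot and capped at 1.

One adjustment is applied on top: the plain percentile interval of a mean is
too narrow in small samples (it implicitly uses a z reference and the 1/n
bootstrap variance), which inflates two-tailed rejection rates to ≈0.07 at
n = 20.  We therefore use Hesterberg's (2015, *The American Statistician*)
expanded percentile: resampled deviations from their mean are scaled by
`sqrt(n/(n−1)) · t_{df,0.975} / z_0.975` before quantiles and sign
proportions are taken (df = n−1 for means, n−2 for moderation slopes).  Under
normality this makes the percentile test match the t reference exactly; the
package's simulations measure type-I ≈ 0.05–0.06 at 20 subjects where the
uncorrected version gives ≈ 0.075.  The expansion factor is ≈1.10 at n = 20
and →1 as n grows, so large-sample behaviour is unchanged.  BCa was
deliberately not used: the expansion addresses the narrowness bias directly,
keeps the sign-proportion p-value, and has no acceleration estimate to go
wrong at small n.

Note a practical floor interaction: with B resamples no p can be below 2/B,
so voxelwise thresholds must satisfy 2/B < p_threshold (hence the 10,000
default against the 0.001 map threshold) and Bonferroni small-volume
corrections over V voxels need 2V/B below the corrected alpha.

## Thresholding, clusters, small-volume correction

Maps are thresholded at uncorrected p < 0.001 and labelled into connected
components (26-connectivity by default, 6/18 available); clusters below 5
voxels are discarded.  Positive and negative effects are clustered
separately so a signed map cannot merge across a zero crossing.  A-priori
ROIs are tested by Bonferroni correction across the voxels of a 10-mm-radius
sphere around the ROI center (membership by voxel-center distance in mm
space).  Bonferroni was chosen over random-field-theory FWE deliberately: it
is conservative, exact under any dependence, and dependency-free.  Default
ROI centers are the standard valuation-system and anterior-prefrontal
coordinates ([−2, 48, −16], [12, 10, −16], [28, 50, −8] in MNI mm); on
synthetic grids the planted-blob center (0, 0, 0) is used.  A voxel with a
significant indirect effect is classified as *partial* mediation if the
direct path c′ is also significant, otherwise *full*.

## Single-trial GLM and trial QC

One regressor per trial: a boxcar at the tasting onset (3 s by default; an
8-s mode reproduces the whole-swirl variant) convolved with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, peak:undershoot 6:1, 32 s
support, unit peak), rendered on a 0.1-s grid and resampled at the TR
(2.5 s).  Nuisance regressors: 24 motion-derived columns — the 6 realignment
parameters, their within-run mean-centred squares, their first differences
(zero at each run's first volume) and the squared first differences — plus a
run intercept and a within-run linear drift per run.  The drift regressors
stand in for high-pass filtering; no separate filter is applied, to avoid
double correction.  Estimation is plain OLS per voxel (no AR prewhitening).

Trial QC uses the variance inflation factor of each trial regressor against
the nuisance set, `VIF_k = 1/(1 − R_k²)` with R² the (centred) determination
coefficient; trials with VIF ≥ 2.5 are flagged and excluded listwise
downstream.  The regression-based VIF is verified against the inverse
correlation-matrix diagonal in the tests.  Peristimulus time courses are
estimated with an FIR basis (one delta regressor per TR-spaced bin per
condition, OLS, classical standard errors).

## Synthetic-study generator

The generator is first-class, tested code that defines the study conditions:

- **Design**: 3 price × 2 payment × 18 repetitions (6 per wine) = 108 trials
  in 3 runs of 36, pseudo-randomized by backtracking search with restarts
  under the constraints: never the same wine on successive trials, at most
  two successive repeats of a price or payment level, exact cell balance per
  run.  Jittered intervals (ISI 6–8 s, mid-trial 6–8 s, ITI 7–9 s, uniform)
  plus fixed event durations put one trial at ≈47 s and one run at ≈28 min.
- **Subjects**: (a_i, b_i) bivariate normal with means (0.5, 0.4), SDs 0.3
  and covariance 0.05 (correlation ≈0.56), so the true group indirect effect
  is 0.5·0.4 + 0.05 = 0.25; direct effect c′ ~ N(0.2, 0.1); rating intercept
  ~ N(5, 1).  The moderator is w_i = λ·a_i + η (λ = 1, SD(η) = 0.1).
- **Trials**: m_t = a_i·x_t + e_m and y_t = intercept_i + b_i·m_t + c′_i·x_t
  + γ_wine·wine + γ_pay·pay + e_y with unit trial noise by default.  Ratings
  are continuous; a 9-point discretization is deliberately not applied by
  default because clipping biases linear path recovery.
- **BOLD**: mediator voxels (a compact central blob) carry the per-trial
  mediator amplitude times the HRF-convolved 3-s boxcar; all voxels receive
  per-voxel linear drift, stationary AR(1) noise (φ = 0.3, innovation SD
  0.5) and a random linear combination of 6 random-walk motion traces.  All
  randomness is seeded; outputs are bit-reproducible.

What the generator does *not* emulate: physiological noise, swallowing
artifacts, susceptibility dropout, spatial autocorrelation of noise, slice
timing, or spatial preprocessing.  Passing tests therefore demonstrate
statistical correctness of the estimation chain under the stated noise
model, not robustness to every artifact of real acquisitions.

## Behavioral model

The rating model is a linear mixed model with 12 fixed effects — intercept,
trial number (1..36 within wine, in tasting order), wine, price, payment,
the six listed two-way interactions and trial×price×payment — and a random
intercept per subject, estimated by maximum likelihood (statsmodels MixedLM),
so deviance = −2·loglik and AIC/BIC are likelihood-based.  All regressors
are z-scored across trials within subject using the sample (n−1) SD;
interaction columns are products of the z-scored main effects; wine and
price are coded numerically (1, 2, 3) before scaling.  Fixed-effect t
statistics use residual degrees of freedom df = n_obs − 12 (no Satterthwaite
correction).  The blind-baseline contrast is a paired two-tailed t-test on
per-subject differences (df = n − 1); the generator's blind session draws
ratings with the cue set to zero.

## Problem sizes and runtime

The acceptance script runs, per invocation: 1,000 design seeds; 1,000
random path matrices and 300 random regression triples for the identities;
100 random VIF designs; 1,000 null datasets of 20 subjects (1,000 resamples)
for type-I; 200 replicates of 30 subjects (2,000 resamples) for CI coverage;
one full BOLD→GLM→mediation study of 30 subjects on a 10×10×10 grid with
25,000 resamples (chosen so the p floor clears both the 0.001 threshold and
the ~515-voxel sphere Bonferroni); 200 planted and 1,000 null moderation
replicates; and one 30-subject behavioral fit.  The voxelwise bootstrap is
computed in voxel chunks to bound memory.  Total ≈1 minute on one CPU; the
full default CLI pipeline (20 subjects, 6×6×6 grid, 10,000 resamples) runs
in ≈15 s.

## Known limitations

- The group summary is the unweighted mean of subject coefficients; no
  precision weighting or hierarchical shrinkage.
- Bonferroni SVC is conservative relative to random-field FWE, particularly
  on smooth maps.
- The expanded-percentile p is calibrated for the mean/slope statistics used
  here; it is not a general replacement for studentized bootstraps.
- Voxelwise inference treats voxels independently; no spatial model.
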