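# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic tests demonstrate.

## Model and procedure

A trial is an ordered sequence of compass bearings θ₁…θ_N (degrees).  Its
turning angles Δθ_t = θ_t − θ_{t−1} are wrapped to (−180°, 180°], positive
counter-clockwise.  Straightness and turn consistency are the mean vector
lengths R_θ and R_Δθ (modulus of the mean unit vector; rotation-invariant).
Internally cued movement is modelled as a correlated random walk (CRW): a
uniform random initial bearing followed by i.i.d. zero-centred turning
angles.  Because R_θ under CRW is driven entirely by the Δθ distribution,
every trial is gauged against the CRW expectation *conditional on its own
turn consistency*.

**Theoretical nulls.**  For each study design (N_obs ∈ {21, 90, 180, 300})
and each fundamental distribution — von Mises with concentration κ on the
grid 0, 1, …, 399, or wrapped Cauchy with 400 ρ values evenly spanning
[0, 0.999] — 1000 CRW walks are simulated per grid point.  Per grid point
we record the mean R_Δθ (the abscissa), the mean R_θ, and the 5th, 10th,
20th, …, 90th, 95th quantiles of R_θ.  One curve per quantile level plus
the mean curve is then smoothed over the abscissa and the observed pair
(R̂_Δθ, R̂_θ) is scored by evaluating the 11 contours at R̂_Δθ and
interpolating the level piecewise-linearly in R_θ; below the 5th contour Q
falls linearly to 0 at R_θ = 0, above the 95th it rises linearly to 100 at
R_θ = 1, then clamps.  ΔR = R̂_θ minus the mean curve at R̂_Δθ.

**Permutation null.**  Per trial, the observed Δθ sequence is permuted
uniformly at random without replacement (100 replicates, duplicates
allowed — unavoidable for short sequences), bearings are rebuilt from the
observed initial bearing (irrelevant to R_θ by rotation invariance), and
Q_r is the percentage of replicates with R_θ strictly below the observed
value.  Ties count against the trial, a conservative convention.

**Selection.**  Drifting-chamber trials must exceed 90% of their nominal
observation count (rejected at n ≤ 81/162/270 for nominal 90/180/300) and
are trimmed to the nominal count keeping the later observations;
diver-followed trials need at least 21 observations and are likewise
trimmed from the front.  Only trials rejecting circular uniformity
(Rayleigh test, p < 0.05) enter the quantitative analyses.  Subsampling a
long trial to 21 observations uses deterministic evenly spaced indices
including both endpoints — emulating the coarser 30-s cadence on the same
track; the original selection rule for subsampling was not recorded, so
results on subsampled designs are comparable in distribution, not
trial-by-trial.

**Meta-analysis.**  Observed quantile samples are tested against the
uniform null with Pearson chi-square on fixed bins — pooled across species
(0–50, 50–70, 70–90, 90–100], expected proportions .5/.2/.2/.1, n ≥ 50;
within species (0–50, 50–75, 75–100], .5/.25/.25, n ≥ 20 — refusing to run
whenever an expected count would fall below 5, with no continuity
correction or exact-test substitution.  Expected counts come from the bin
widths: quantiles are probability-integral transforms of the null, so
their null distribution is uniform by construction and simulating the
expectation would only add noise.  Effect size is Cohen's W = √(X²/n)
(≥ 0.5 treated as strong).  Across species, a one-sided one-sample t-test
asks whether mean W exceeds 0.5, preceded by a Shapiro–Wilk normality
check; non-normality warns and adds a one-sided Wilcoxon signed-rank p as
a sensitivity line rather than aborting.  Group trials are excluded from
the species-level test.  Q_vm and Q_r are cross-tabulated in a 20×20
matrix of half-open 5% bins (Q = 0 in bin 1).

## Numerical choices

* **Angles** are degrees at every interface and radians internally.
  Bearings wrap to [0, 360); turning angles to (−180, 180].
* **Rayleigh p-value** uses the second-order series
  p ≈ e^{−Z}[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
  Z = nR², validated against a 100,000-replicate Monte-Carlo null; the
  approximation error is well inside ±0.02 at n = 21.
* **Samplers.**  Von Mises draws use the Best–Fisher rejection sampler
  (numpy), with κ = 0 special-cased to circular uniform.  Wrapped Cauchy
  uses the exact inverse-CDF transform
  θ = μ + 2 arctan(((1−ρ)/(1+ρ)) tan(π(U−½))), so the population resultant
  equals ρ exactly.
* **Contour fitting.**  The per-grid-point summaries are smoothed with
  cubic smoothing splines (generalized-cross-validated penalty).  Grid
  points crowd together as the abscissa approaches 1, which makes a spline
  in R_Δθ ill-conditioned, so both coordinates are smoothed over the
  uniformly spaced concentration index and the parametric curve is
  resampled onto a dense 512-point abscissa grid.  Contours are then
  projected to be non-decreasing in R_Δθ and ordered across levels —
  monotonicity is required for the quantile inversion to be well defined.
  Diagrams serialize to JSON (grid summaries, dense contour samples, seed,
  format version) and are cached per (distribution, N_obs, n_rep, seed).
* **Degenerate inputs.**  Constant-turning trials give a degenerate
  permutation null (all values equal; warned).  A zero-variance species-W
  sample makes the t statistic 0/0; the convention is sign-aware: mean at
  the reference → t = 0, p = 0.5; mean above (every species at the
  effect-size ceiling √3 under the species bins, e.g.) → t = +∞, p = 0,
  the limit scipy also returns.  Single-trial groups report an undefined
  confidence interval rather than zero width.
* **Seeding.**  All randomness flows through one `numpy.random.Generator`;
  pipeline-level fits spawn per-stage child seeds from a master
  `SeedSequence`, so reruns with the same seed are bit-identical.

## Synthetic cohorts

The generator produces the archetypes the analysis assumes or probes, all
cumulated from a uniform initial bearing: CRW (von Mises or wrapped Cauchy
turns), biased random walk (bearings i.i.d. around a fixed goal), biased-
correlated walk (turn attracted toward the goal with weight w ∈ [0, 1];
w = 0 reduces to CRW), one-sided bias (turns centred on δ ≠ 0), zigzag
(turns alternating deterministically around ±δ; a random-sign variant is a
flag), and composite CRW (turn concentration switching between two values
by a symmetric two-state Markov chain with geometric dwell times).  Default
study shapes mirror the field designs: 21 observations per diver-followed
trial, 90/180/300 for chamber trials, cohorts of ~14 species × 20 trials.
For power and null-error checks the bias concentration is 2 (a moderately
capable orienter) and the pure-CRW turn concentration is 10, chosen so the
Rayleigh pre-filter retains roughly the fraction of trials the field
studies report as directional (~90%) and therefore distorts the null
quantile distribution no more than it does on real data.

What the synthetic cohorts do *not* emulate: measurement error in
digitised bearings, missing frames, within-trial behavioural switching
(except the composite archetype), group interactions, 3-D movement
projected to 2-D, and drifting cue sources.  Passing tests therefore
demonstrate the statistical machinery — calibration of the nulls,
power against biased walkers, refusal rules — not field validity for any
particular species.

## Known limitations

* **Tail calibration of the theoretical quantile.**  The contours are
  per-concentration *marginal* quantiles of R_θ placed at the mean R_Δθ,
  but each trial is evaluated at its own noisy R̂_Δθ, which is positively
  correlated with R̂_θ within a concentration.  Where the contour slope
  exceeds the within-concentration conditional slope (the steep
  high-concentration region), straight trials are scored against an
  elevated threshold.  The result, measured on CRW cohorts at N_obs = 21,
  is a mild compression of the extreme deciles (top decile holds ~6–8%
  instead of 10%) while the bulk of the distribution and the pooled
  chi-square error rate stay near nominal.  This is a property of the
  phase-diagram construction itself, shared by any scattered interpolation
  of the same contour set; a conditional-on-R_Δθ quantile surface would
  calibrate better but would be a different statistic.  Consequence for
  inference: individual-trial quantiles near the extremes are slightly
  conservative for detecting orientation (biased toward the centre), so
  species-level conclusions should rest on the binned tests, which are
  dominated by the well-calibrated 50th/75th bin edges.
* The permutation null is coarse for short trials (100 draws from at most
  (N−1)! orderings, with duplicates), so Q_r has ±5-point granularity
  noise at N_obs = 21.
* Quantiles outside the 5th–95th contours rely on the linear-tail
  convention; trials at the very edge of the simulated support are clamped
  (with a warning) and their Q is less certain.
* The chi-square layer treats trials as exchangeable within species;
  covariates (location, turbidity, ontogeny) are out of scope, as are
  mixture models distinguishing biased from biased-correlated walks.
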