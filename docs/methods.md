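# Methods

## Surface model

Surfaces are zero-mean periodic height fields h(x, y) on an n×n grid
(default n = 1024, physical size 50 mm, pitch ≈ 0.049 mm) synthesized as a
superposition of Fourier modes.  The per-mode height amplitude A(q) is a
deterministic function of the wavevector magnitude q:

* plateau: A(q) = const for 2π/λ_long ≤ q ≤ 2π/λ_roll (defaults
  λ_long = 25 mm, λ_roll = 7 mm);
* power law: A(q) = A_plateau · (q/q_roll)^(−1−H) for
  q_roll < q ≤ 2π/λ_short (default λ_short = 0.5 mm), continuous at the
  rolloff.  The isotropic power spectral density then scales as
  q^(−2−2H), the standard self-affine convention, and the
  height-difference correlation decays toward small distances with
  exponent H;
* zero outside the band and at q = 0 (this enforces the zero mean).

Randomness enters only through mode phases, i.i.d. uniform on [0, 2π)
with conjugate symmetry (phase(−q) = −phase(q)) so that heights are real.
The phase seed therefore *is* the topographic structure: two surfaces
sharing a seed share their hills and valleys regardless of H, because the
plateau modes (which carry the large features) have identical amplitudes
and phases.  Each surface is individually rescaled to the target rms
height (0.4 mm), which is exact by construction.

A consequence of deterministic amplitudes worth knowing: every statistic
that depends only on the amplitude spectrum — rms curvature, rms slope,
the expected correlation curve — is *identical* across topography
families at fixed H (Parseval), not merely similar.  The nine-sample
matrix therefore has three distinct κ values.  Printed physical
realizations of such surfaces would reintroduce per-sample variation
through fabrication and measurement; the package makes no attempt to
model that, and per-sample κ tables measured on physical prints
(κ ≈ 1–3.5 mm⁻¹) are not comparable to the computational κ of the
definition files at full pitch (κ ≈ 4–8.4 mm⁻¹ under the defaults here;
the second-difference κ is dominated by the shortest wavelengths, so its
absolute scale is resolution-sensitive).

Phases come from `numpy.random.default_rng` (PCG64), recorded in each
surface's provenance; identical (seed, spec) reruns are bit-identical.

## Roughness statistics

The height-difference correlation is
G(d) = √(⟨(h(r+d) − h(r))²⟩ / 2), averaged isotropically over periodic
lattice offsets binned by Euclidean length (half-pixel tolerance); a
cross-section variant averages offsets along one axis only.  The factor
1/2 makes the large-distance plateau equal the rms height (0.4 mm) for
uncorrelated points; a "raw" normalization (√2 larger) is available.

κ and the rms slope use central second/first differences with periodic
wrap at the grid pitch.  The mixed second derivative is deliberately
excluded from κ.  Both converge at second order in the pitch (verified on
sinusoids against closed forms) and scale linearly with height rescaling.

**Hurst estimation.**  Two estimators are provided:

* `estimate_hurst` — least-squares slope of log G vs log d over a window
  (default 0.6–3 mm, inside the power-law band).  Exact on pure power-law
  curves, but *biased on the default study band*: with power-law content
  only between 0.5 and 7 mm, the curve bends toward ~d¹ scaling below
  λ_short and saturates toward the plateau above ~λ_roll/2π ≈ 1.1 mm, and
  these crossovers overlap.  Measured bias at the default window is
  −0.07 (H = 0.4) to −0.29 (H = 0.8); no window removes it for all H.
* `fit_hurst_bandlimited` — fits the measured curve against the exact
  phase-averaged expectation of G for the generating spectrum family
  (plateau and cutoffs fixed, H free), by scalar minimization of the
  log-space residual.  Because the band limits are part of the surface
  definition, this estimator is unbiased for these surfaces and recovers
  planted H to better than ±0.01 at the default grid; it is the one used
  for quantitative recovery.  It assumes the band limits are known, so it
  is an estimator for *these* surfaces, not a general-purpose one.

## Synthetic observer

The observer generates the data shapes of the three study arms:
visual (15 participants × 50 triplets), tapping (10 × 28) and sliding
(13 × 28), each participant answering a seeded random subset (without
replacement) of the 252 reference × unordered-pair triplets of the nine
samples, with randomized left/right placement.

Decisions follow a logistic choice model on the planted dissimilarity
D(α_true): P(left) = σ((D_right,ref − D_left,ref)/σ_noise), with an
optional probit link and lapse rate (default 0).  The choice model is a
modelling decision of this package — the minimal monotone model
consistent with the likelihood used for embedding — not something the
study data pin down.  Defaults: α_true per arm equals the salience
reported for that arm (2.68 / 1.22 / 0.97 mm⁻¹ for visual / tapping /
sliding); decision noise σ = 0.7 mm⁻¹, chosen once so that the implied
0.75-threshold (σ·ln 3 ≈ 0.8 mm⁻¹ on the metric scale) matches the
sliding-touch just-noticeable difference in curvature.

Friction trials use a planted linear law μ(κ) = 0.31 + 0.04·κ, anchored
at μ = 0.35 for κ = 1 mm⁻¹ and μ = 0.45 for κ = 3.5 mm⁻¹, plus an
additive per-participant offset (sd 0.05) and per-measurement noise
(sd 0.02).  Offsets cancel within a trial's comparisons, mimicking
participants with individually higher or lower skin friction.  In the
sliding arm the observer "reads" curvature through its own noisy friction
measurements (perceived Δκ = Δμ/0.04) and combines them with the
topography term, so the recorded per-trial friction coefficients are
exactly the values that drove the decisions — the statistical coupling
the friction-based psychometric analysis assumes.  Force traces for the
friction oracle are circular sliding at constant μ:
(Fx, Fy) = μ·Fz·(cos θ, sin θ), θ advancing at ~0.7 cycles/s.

What the generator does *not* emulate: participant-specific perceptual
scales or biases, learning/fatigue over trials, reaction times,
skin-mechanics, and any coupling between topography and friction.
Passing recovery tests therefore demonstrates that the *analysis chain*
is correct and well-conditioned at the study's sample sizes — not that
the choice model describes human deciders.

## Ordinal embedding

Coordinates of the nine samples in n dimensions (default 3) maximize the
sum of log choice probabilities under the same logistic link, plus a weak
Gaussian prior on the coordinates (weight 0.2 against hundreds of
decision terms).  The prior fixes the scale/likelihood trade-off and
keeps pairwise distances from saturating arbitrarily when decisions are
near-deterministic — without it, distances beyond the noise scale are
unconstrained, which distorts the linear correlation the α fit relies
on.  Optimization is multi-start L-BFGS (default 16 seeded Gaussian
starts; best likelihood wins, ties by start index) with analytic
gradients.  Reported coordinates are centered with unit rms norm; the
stored `link_scale` compensates so the reported likelihood is exact.

Dimensionality is assessed by seeded k-fold cross-validation (default
k = 10) on mean held-out log-likelihood per decision (fraction correct
also reported), with a one-standard-error selection rule.  Reliability is
assessed by bootstrap: resample decisions with replacement, refit, and
report the coefficient of variation of normalized pairwise distances per
sample pair and on average.  Procrustes alignment applies the orthogonal
rotation whose first axis maximizes the Pearson correlation between
dimension-1 coordinates and the per-sample Hurst exponents (closed form:
the least-squares direction, completed to an orthonormal basis), sign
fixed so H increases along +dim1; distances are untouched.

## Dissimilarity metric

D_ij = √((κ_i − κ_j)² + (α·[topo_i ≠ topo_j])²) is a true metric for any
α ≥ 0 (it embeds isometrically in 3D: the κ axis plus an equilateral
topography triangle of side α); the triangle inequality is verified
exhaustively in the tests.  α is fitted by maximizing the Pearson
correlation between the 36 pairwise D values and the embedding distances
— a 1000-point grid scan on [0, 10·max|Δκ|] refined by bounded scalar
optimization, ties toward smaller α.  Correlation is invariant to shifts
and positive scalings of the embedding distances, so no normalization of
the embedding is needed.  A linear variant |Δκ| + α·[differ] is provided
for comparison; on data generated from the Euclidean form it correlates
no better than the Euclidean fit.

## Psychometrics

Stimulus intensity is S = |D_left,ref − D_right,ref| (metric-based) or
S = ||μ_l − μ_ref| − |μ_r − μ_ref|| (friction-based, per-trial
coefficients).  Sorted intensities are split into equal-count bins
(default 10; sizes differ by at most one); each bin contributes its mean
S and the fraction of decisions matching the prediction.  Exact ties in
the predicted side are excluded and logged — with deterministic
amplitudes the sample matrix has exactly tied pairs, so this case is
routine, not pathological.  The Weibull sigmoid P = 1 − 0.5·exp(−(kS)^d)
is fitted by bounded nonlinear least squares on the binned proportions
(grid-search fallback); R is the Pearson correlation between fitted and
observed proportions.  The JND at level p is ((−ln 2(1−p))^(1/d))/k,
verified against numerical inversion to 10⁻¹⁰.

Agreement rates score only unbiased triplets: both alternatives share
one structural property (H or topography) and exactly one shares the
other with the reference.  Significance versus chance uses the exact
two-sided binomial test.

## Numerical and design choices

* All per-stage seeds derive from one global seed via
  `numpy.random.SeedSequence.spawn`.
* Correlation distances must lie between the pixel pitch and half the
  surface size; sub-pitch separations raise.
* Friction traces discard time points with Fz below 0.1 N (lift-off);
  the trial coefficient is the mean of pointwise μ(t) = F_f/Fz
  (the printed-equation reading), with a ratio-of-means option.
* σ_noise = 0 decisions are deterministic argmins with fair-coin ties.
* The end-to-end recovery checks (embedding-distance correlation, α and
  JND recovery) are evaluated as means over five replicate synthetic
  experiments: a single 13×28 experiment estimates α with ~20% sampling
  sd, so single-draw checks at tight tolerances would measure seed luck
  rather than correctness.  Replication leaves the study conditions
  unchanged.
* Problem sizes in the tests: module tests use 256² grids (same spectral
  band, faster FFTs); the acceptance script and generator-level checks
  use the full 1024² defaults.

## Known limitations

* The Bayesian formulation behind the original embedding method is not
  reproduced exactly; the likelihood here is a generic maximum-likelihood
  stand-in with an explicit link and prior.
* The cross-validation score (held-out log-likelihood) is one reasonable
  choice among several; no claim is made to reproduce any particular
  published curve's y-axis.
* Human-data-dependent numbers (agreement percentages, per-arm α values
  and JNDs, bootstrap CoVs of the real experiments) cannot be reproduced
  from synthetic data; the pipeline reproduces the *procedures* and
  recovers planted values.
* The band-limited Hurst estimator presumes the generating band; applying
  it to surfaces with different cutoffs requires passing their spectrum.
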