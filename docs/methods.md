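# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `charrdev`. It is the
package's own account of its statistics; every empirical statement below
is one the test suite or `scripts/acceptance.py` actually computes.

## The scientific setting

Two sympatric morphs of a northern freshwater fish — a planktivorous (PL)
and a small-benthic (SB) form — and their pooled F1 hybrids are reared in
a common garden: full-sib families nested within cross types, individuals
followed over four developmental stages indexed by thermal age
(degree-days, °C·d). The questions are (i) whether the crosses differ in
mean growth, developmental timing and behaviour, (ii) whether they differ
in the *structure* of phenotypic (co)variation — summarized by the
phenotypic variance–covariance matrix **P** over seven focal traits — and
(iii) whether head shape covaries with those traits beyond shared
allometry. Under common-garden rearing with family effects controlled,
**P** serves as an observable surrogate for the genetic covariance
structure.

## Synthetic-data generator

The generator is first-class, tested code: its parameters are the ground
truth every estimator is validated against.

**Design.** Defaults: 3 cross types (PL, SB, F1 with reciprocal hybrid
crosses pooled; reciprocal simulation is a config flag, off by default),
3 full-sib families per cross, 40 offspring per family (360 fish), stages
at 445, 530, 840 and 1100 °C·d, and 3 behavioural trials per individual.

**Traits.** Individual trait vectors over the seven focal traits
(standard length at hatching and at first feeding on the log10 scale,
two growth increments, relative yolk area, yolk conversion, log feeding
latency) are cross mean + family effect (drawn once per family) +
individual effect + per-record residual, with all covariance matrices
validated symmetric PSD. Longitudinal stage lengths are defined *from*
the size and growth traits (length at stage 2 = length at stage 1 + the
first growth increment, and so on), plus log10 measurement noise of 0.01,
so the trait table and the growth curves describe one consistent fish.

**Default parameter values.** Growth polynomials are on log10 mm against
thermal age rescaled to [0, 1] over the 445–1100 °C·d window (for
numerical conditioning): PL (1.23, 0.52, −0.10), SB (1.20, 0.42, −0.14),
F1 (1.20, 0.43, −0.12) — hatching near 17 mm, 26–48 mm at the end of
rearing, with the SB-like cross and hybrids slower and more decelerating.
Cross means of the size/growth traits are derived from these curves so
the two descriptions agree exactly. Mean-standardized trait variances
follow the reported per-cross pattern of the study system — largest in
SB (post-feeding growth variance 0.68), smallest in the hybrids — with
modest correlations (0.2–0.45) among the size/growth traits and a small
yolk correlation; the raw-scale covariance is back-scaled by the trait
means so the standardized **P** equals this target. Family effects have
2% CV per trait. These standardized variances are large in absolute
terms (CV ≈ 30–80%); they are adopted as the study conditions rather than
re-scaled to look conventional, and the analysis chain is exercised at
exactly this dispersion.

**Behaviour.** The binary feeding propensity comes from a probit latent
Gaussian: cross mean + individual effect + trial residual, thresholded at
zero. Defaults give PL a true latent repeatability of 0.4
(V_ind = 2/3, V_res = 1) and the other crosses ≈ 0, with observed
feeding proportions near 0.7. Attack counts are log-link Poisson with a
lognormal individual effect (the distributional family of counts is an
assumption of this package; nothing in the study system pins it down).
Foraging zone is multinomial with fixed probabilities. The paper-style
logit latent scale is replaced by probit throughout (conjugate with the
Gibbs engine); latent-scale repeatabilities are link-consistent
internally, and the usual ≈1.6 scale factor relates probit to logit
coefficients if needed.

**Landmarks.** Each fish × stage gets a 20-landmark head configuration:
a deterministic template (3 fixed landmarks + 13 dorsal head-curve and 4
eye semilandmarks, unit centroid size) + an allometry field × (log
centroid size − mean) + iid coordinate noise (SD 0.01), scaled to the
individual's true head size (45% of standard length) and then randomly
rotated and translated; the nuisance parameters are returned for
invariance tests. The allometry field is projected into the Procrustes
tangent space of the template (orthogonal to translations, rescaling,
rotation), so the injected direction is exactly expressible by
superimposed shapes; the zero-noise test recovers it with vector
correlation > 0.99 after rotating into the consensus frame. Optionally a
dense head curve, a yolk-sac ellipse (area = relative-yolk trait × SL²)
and the notochord-tip point are attached so standard length and yolk
area can be re-measured from the synthetic digitization (the re-measured
standard length is accurate to ~2%; the residual is the transverse
offset of the farthest head point).

**Onset of feeding.** Daily one-zero records around a per-individual
onset day (cross mean + family + individual deviation, detection
probability 0.7 after onset, 2% never-feeders). This generator is an
addition beyond the core trait/behaviour/shape trio so the pipeline's
onset stage has an input.

## Morphometrics

- *Semilandmarks* are extracted by equidistant arc-length resampling of
  piecewise-linear curves, endpoints preserved; no sliding (a stated
  non-goal).
- *Yolk area* is the absolute shoelace area of the 200-point outline;
  self-intersection is not checked.
- *GPA* uses full Procrustes superimposition: centring, unit
  centroid-size scaling, and 2-D SVD rotations with reflection excluded;
  tolerance 1e-10 on the consensus change, maximum 100 iterations (error
  with diagnostics on non-convergence). Aligned coordinates are
  dimensionless; raw units survive only in centroid sizes, lengths and
  areas. The consensus orientation is arbitrary (set by the first
  configuration), which matters only when comparing loading vectors
  across frames — rotate first.
- *Disparity* is the mean squared Procrustes distance to the group mean;
  pairwise differences are tested by permuting group labels.
- *RRPP* computes sequential (type-I) sums of squares over the shape
  coordinates via orthonormal bases of the nested column spaces; each
  term's null permutes the reduced model's residuals, Z standardizes the
  observed SS against the permuted SS, and p includes the observed value
  (p ≥ 1/(n_perm+1), default 999 permutations). Nested family terms are
  permuted under the same reduced-model scheme — the exact scheme for
  nested terms is a genuine open choice, and this is the one
  implemented.
- *Trajectory analysis* summarizes each group's stage-mean sequence by
  path length, first principal axis, and size-standardized trajectory
  shape; permutation is at the subject level when subject identifiers are
  given (keeping an individual's stages together), otherwise stratified
  within stage.

## The mixed-model engine

A Gibbs sampler for y_i = M_i β + Σ_k z'_{k,i} U_{k,l(i)} + e_i with
e ~ N(0, R) and vec(U) ~ N(0, G_k): matrix-normal/blockwise normal full
conditionals for β (vague N(0, 1e8) prior; rank-deficient designs are
rejected), level-wise normal full conditionals for the random effects
(batched Cholesky across levels), and inverse-Wishart full conditionals
for G and R sampled by Bartlett decomposition from the chain's own
generator (bit-reproducible under the chain seed). Per-response design
matrices are supported (the yolk model pairs each stage's area with its
own log-length covariate). Binary responses use truncated-normal
latent-variable augmentation with the residual variance fixed to 1
(probit identifiability). Priors follow the weakly-informative
inverse-Wishart convention (scale V, belief nu; nu must exceed the
dimension minus one for propriety — nu = number of traits for
multi-response models, 0.002-style for scalars).

**Flat-direction sweep.** When a fixed-effect column is expressible in a
random term's basis on a group of levels (cross-level growth coefficients
vs family/individual deviations), the Gibbs chain mixes extremely slowly
along the direction "shift the coefficient, compensate all effects". The
engine adds a translation-group move (a generalized Gibbs step): per
group it draws a shift c from the conditional density along that orbit —
c ~ N(GLS projection of the mean effect onto the basis, (J B'G⁻¹B)⁻¹) —
subtracts B c from the effects and adds c to the coefficients. The
likelihood is invariant and the move is exact; effective sample sizes
for the growth coefficients rise about tenfold. Chains are initialized
at the per-response OLS solution with small random-effect covariances, a
near-likelihood start that also keeps nearly-noise-free fits out of a
drifted quasi-mode that the wide default initialization can wander into.

**Summaries.** Posterior modes are the argmax of a Silverman-bandwidth
Gaussian KDE on a 512-point grid, refined by a quadratic fit to the
log-density around the peak (this removes most of the argmax jitter; at
1e5 standard-normal draws the mode is within ±0.01 of zero). HPD
intervals use the sorted-window (shortest-interval) algorithm. Both
require ≥ 100 draws. Default chain: 50,000 iterations, 10,000 burn-in,
thinning 20; tests and examples use shorter chains and report effective
sample sizes rather than asserting convergence.

## Stage-level models

- *Growth* is a per-cross quadratic in scaled thermal age. When all fish
  share the same few stages (≤ 6), random effects are placed at the
  stage level with unstructured covariance for both family and
  individual — this nests polynomial deviations and keeps the implied
  within-individual covariance fully flexible, which the intercept/slope
  basis cannot (its restriction demonstrably narrows the cross-level
  intervals below their frequentist spread); with irregular ages it
  falls back to intercept+slope deviations, and to intercepts only when
  fewer than three time points identify a slope. The individual-level
  prior is a small floor (1e-5); the family level, identified by only a
  handful of clutches, gets a weakly-informative scale at 1% of the
  within-(cross × stage) variance with nu = d + 0.002 — heavy-tailed
  (infinite prior mean), it keeps cross-level contrasts honestly
  uncertain instead of collapsing the clutch variance toward zero. In a
  50-replicate recovery study at the default scale, each generating
  coefficient falls inside its 95% CrI in ≥ 90% of replicates
  (asserted in the test suite).
- *Yolk sac*: bivariate response (areas at the first two stages), each
  with its own intercept, its stage's log-length covariate and cross
  contrasts against the PL baseline; family random intercept shared
  across responses. *Yolk conversion* is defined here as
  (area_D1 − area_D2) / ((length_D2 − length_D1) · area_D1) — relative
  yolk consumed per unit growth — isolated in one function because the
  trait has no canonical definition; likewise *relative yolk area* is
  area/SL². Both are explicit package choices.
- *Onset of feeding*: first day with a recorded feeding event;
  never-feeders are flagged censored and excluded from the Gaussian
  mixed model on dates (no survival modelling).
- *Repeatability*: latent R = V_ind/(V_ind + V_res) per draw; for probit
  binary traits the data-scale R integrates p(u) = Φ((μ+u)/σ_e) over
  u ~ N(0, V_ind) with 61-node Gauss–Hermite quadrature, forming
  between- and within-individual observed-scale variances and their
  ratio (the Jensen's-inequality-aware route; it matches a 10⁶-draw
  Monte-Carlo transform within 0.01). Counts use closed-form
  lognormal-Poisson moments; since counts are *fitted* as Gaussian on
  log1p, their data-scale transform is approximate. Latency is treated
  as log-normal (modelled on the log scale, trials averaged where a
  single value per fish is needed). Significance is read as the 95% CrI
  lower bound against zero. Foraging-zone use is reduced to three binary
  propensities fitted separately.

## P matrices

Each cross's **P** is the posterior of the individual-level covariance
from a 7-trait multi-response model: traits mean-standardized by group
means, family as a *fixed* effect (too few clutches to estimate a family
covariance), individual identity as the random effect, and the residual
fixed to 1e-6 × trait variance because each trait has one record per
fish — the individual covariance absorbs the phenotypic signal. The
individual-level prior scale is 0.01·I with nu = 7.002, negligible
against the data at n ≈ 120. Numerically non-PSD draws are clipped to
the PSD cone (count logged).

Summaries per draw: V_tot = Σλ (verified equal to the trace to 1e-10),
Ω = λ₁/λ₂ (the wording "ratio of the first two eigenvalues" is taken
literally; λ₁/mean(λ₂…) is *not* used), and θ = arccos|v₁·v₂| in
degrees, computed on draws paired by index (the pairing rule is a
package choice) with a warning on nearly-degenerate leading eigenspaces.
The θ null resamples 150 individuals from the pooled pair of crosses and
takes the sample covariance of family-adjusted, mean-standardized
residuals — a deliberate approximation to a full re-fit, adopted for
tractability; pools smaller than 150 fall back to sampling with
replacement and are flagged. Krzanowski's H sums the projectors onto
each group's leading-k eigenvectors per draw (k = 3 by default,
bounded by ⌊7/2⌋); its randomized-group null shuffles cross labels and
rebuilds pseudo-group sample covariances. Ellipsoid projections report
each cross's posterior-mean P in the reference cross's first three
eigenvectors with the captured-variance fraction.

## Two-block PLS

First singular pair of cov(block1, block2) between the (mean-
standardized, latency-averaged) traits and the aligned stage-3 shape
coordinates; r is the Pearson correlation of the paired scores, and the
sign convention makes the largest-magnitude first-block loading
positive. Permutation shuffles the rows of one block (batched SVD over
permutations); effect sizes standardize Fisher-z(r) against the
permutation null (the transformed scale is a package choice and is
swappable), and pairwise cross comparisons divide the effect-size
difference by the pooled unit SEs (√2), with two-sided normal p. A
leave-one-out report flags influential individuals, motivated by the
known sensitivity of such comparisons to single extreme fish. Only the
first singular pair is analysed.

## Pipeline and reproducibility

All randomness flows from one root seed split into stage-keyed streams
(SeedSequence spawn keys), so toggling one stage cannot perturb another.
The manifest records the configuration, stage seeds, package version and
SHA-256 of every output; reruns are byte-identical. The problem sizes in
the tests and the acceptance script (reduced chains of 800–3,000
iterations, 199–999 permutations, 20–500 replicates) are chosen to make
the full validation run in minutes while keeping Monte-Carlo error well
inside the asserted tolerances.

## What the synthetic data do and do not show

The generator reproduces the design structure (nesting, repeated trials,
longitudinal stages), the covariance patterns and the allometric
shape–size coupling of the study system, with Gaussian traits and exact
probit/Poisson behavioural links. It does not emulate mortality or
malformation, egg-stage processes, tank-position effects, measurement
digitization error beyond iid coordinate noise, non-Gaussian trait
distributions, or plasticity in the shape–size relationship. Passing
tests therefore demonstrate that the estimators recover truth under the
stated generating model at the stated sample sizes — not that the same
certainty transfers to real data with outliers, missingness or link
misspecification. Family effects are controlled as fixed effects in the
P models, so family variance is corrected for but never quantified
there; the growth model, by contrast, estimates it and shows how wide
cross-level intervals must be with only nine clutches.
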