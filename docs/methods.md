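# Methods

This note documents the models, estimators and design choices in `anglesel`,
in the spirit of a statistical-software methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The experiment being modeled

Three replicated semi-natural ponds are stocked with 40 PIT-tagged juvenile
carp each. After a 6-day undisturbed observation period, the ponds are angled
4 hours per day for 20 days; landed fish are identified and immediately
released, so every fish remains at risk throughout and recaptures occur. A
fish's *fitness* with respect to the fishery is binary: s = 0 if it was
landed at least once within the horizon (7 days for short-term, 20 for
long-term vulnerability), s = 1 otherwise. Six traits enter the analysis:
boldness as distant-feeding-spot visit rate (BP, visits/hr), total length at
stocking (TL, mm), growth increment over the experiment (G, mm, as residuals
on boldness), body- and head-shape scores (SB, SH, size-corrected PC1 scores),
and sheltering time (SP, min/hr).

## Behavior metrics

Raw antenna reads are collapsed with a debounce window (default 60 s; the
notion of a "visit" is not defined by raw reads, so the window is a
configurable convention and downstream checks use properties robust to it).
Consecutive reads on one feeding-spot antenna closer than the window form one
visit; reads on the shelter antenna closer than the window form one presence
interval whose duration is last-read − first-read, an isolated single read
contributing half a window (midpoint convention). Daily values use the full
24-h day; per-period values are means of daily values, and fish without reads
score 0 rather than missing.

Between-period consistency: Spearman rank correlation (midranks for ties,
t-approximation p-value), and repeatability as the intraclass correlation
from a one-way ANOVA with individuals as groups,

    s²_W = MS_W,  n₀ = (N − Σnᵢ²/N)/(a−1),  s²_A = (MS_A − MS_W)/n₀,
    r = s²_A/(s²_A + s²_W),  F = MS_A/MS_W on (a−1, N−a) df.

The two "measures" are the week-level means (observation week vs first
angling week). Negative estimates are reported as computed — clamping at zero
would bias the estimator in the parameter-recovery tests.

## Morphometrics

Sixteen landmarks per fish (left side) are read from TPS files; the image
y-axis is inverted on read (configurable) so shapes are right side up.
Generalized Procrustes superimposition centers each configuration, scales to
unit centroid size and iteratively rotates to the running consensus (optimal
rotation by SVD of the cross-covariance; reflections disallowed because all
photographs show the same side) until the consensus change falls below the
tolerance (default 1e-10). The consensus is then rotated to a canonical
orientation (principal axes, 180° ambiguity resolved by the x-coordinate
third moment, proper rotations only) so aligned coordinates are exactly
invariant to how inputs were oriented, scaled or translated. Full GPA without
tangent-space projection is used: shape variation in this application is
small, where the difference is negligible.

Dorsoventral arching (a bent posture on the photographing stand) is a
nuisance shape direction. Its default estimate: fit a quadratic to each
fish's midline landmarks (jaw tip, eye, operculum, lateral-line end, and the
dorsal/ventral peduncle midpoint) in aligned coordinates; the signed
quadratic coefficient is the fish's arching score; regressing the aligned
coordinates on that score and normalizing the slope vector gives a unit
nuisance basis. A user-supplied basis overrides the estimate (the literature
leaves the exact construction open, so the package keeps it auditable: the
projector reports the change in PC explained variance as a diagnostic — small
change means arching did not matter). Burnaby projection removes the basis:
`X(I − F(FᵀF)⁻¹Fᵀ)`; it is idempotent and norm-non-increasing.

PCA of the (projected) coordinates uses the covariance eigendecomposition
with a fixed sign convention (largest-magnitude loading positive) for
reproducibility. The head analysis re-runs GPA and PCA on the six head
landmarks; the Burnaby step is applied only to the body analysis — the
arching score is defined by midline landmarks that the head subset lacks, and
bending displaces the head roughly rigidly, which head-GPA absorbs. PC1
scores are size-corrected by OLS on total length; the residuals (exactly
uncorrelated with TL) are the shape traits SB and SH.

## Survival models

All predictors are z-standardized (sample SD, n−1) over the complete-record
fish; quadratic terms are squares of z-scores. Nine candidate logistic
models per horizon — from the full model with quadratic boldness and growth
terms down to growth-only and the intercept-only NULL — are fitted by maximum
likelihood (IRLS, log-likelihood tolerance 1e-8, max 100 iterations;
explicit failures on rank deficiency or separation, with the comparison
continuing over the models that converged).

Pond replication enters as a pond-level intercept. The default is a random
intercept with the Laplace approximation: for fixed effects β and
random-effect SD τ, the conditional modes û_j solve a 1-D Newton problem per
pond, and the marginal log-likelihood per pond is
ℓ_j(û) − û²/(2τ²) − ½log(1 + τ² Σᵢ wᵢ), maximized jointly over (β, log τ)
with L-BFGS-B. On a fixed toy dataset this implementation agrees with
lme4::glmer (Laplace) to ~1e-4 in coefficients, τ and log-likelihood (frozen
in the test suite). Wald SEs come from the observed information of the
marginal likelihood in β. `fixed` (pond dummies) and `none` (pooled) modes
are provided for sensitivity.

The parameter count k used by AICc counts fixed effects including the
intercept only (NULL → k = 1), matching the conventional reporting of such
candidate-set tables; the random-intercept variance is not penalized.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights are exp(−Δ/2) normalized.
The *final* model for gradient reporting is the richest model within
ΔAICc < 1 of the minimum, ties broken toward fewer parameters and then model
order.

## Selection gradients

Logistic coefficients are linearized by the average-gradient transformation:
β_SD,j = α_j · mean[Ŵᵢ(1−Ŵᵢ)]/W̄, with Ŵ the fitted survival probabilities
(conditional on pond modes in the random-intercept case) and W̄ the observed
mean fitness. With z-scored predictors this is already the SD-standardized
gradient; the test suite pins the semantics independently of any formula
variant by checking against a finite-difference derivative of mean relative
fitness. Mean-standardized gradients are β_μ,j = β_SD,j · μ_j/σ_j, using each
trait's stored original mean and SD.

Two conventions deserve note. (1) Growth enters the model as the residual of
the increment on boldness, whose mean is 0 by construction; "doubling growth"
is only meaningful on the raw increment scale, so the pipeline stores the raw
increment mean as μ_G (the residual SD remains σ_G, the unit of α_G). (2)
Shape scores are PCA scores with mean ≈ 0, so their β_μ are ≈ 0 regardless of
α — mean-standardization is uninformative for traits without a natural zero,
which the gradient tables make visible rather than hide. Nagelkerke pseudo-R²
is computed from the final and NULL fits: R²_CS/(1 − exp(2ℓ₀/n)).

## The simulator

The generator's defaults are the study conditions; they are not tuning knobs.

* **Traits.** Multivariate normal over (BP, TL, G, SB, SH, SP) with means
  (4.6, 199, 7.8, 0, 0, 6.3), SDs (1.5, 9.2, 5.4, 1, 1, 2.6) and the
  published 6×6 correlation matrix (BP–G 0.310, BP–SP −0.521, …). The matrix
  is positive definite as printed; an eigenvalue-clipping repair (threshold
  1e-6, rescaled to unit diagonal) guards against rounded user-supplied
  matrices. Rates are floored at zero.
* **Detections.** Daily feeding-spot counts are Poisson with lognormal
  day-to-day noise, `count ~ Poisson(24·BP_i·exp(ε_id))`; the noise variance
  solves the intraclass correlation of weekly means for the target
  repeatability (default 0.6, inside the published 0.53–0.74 range),
  accounting for Poisson noise and the harmonic mean of the two period
  lengths. Sheltering uses a lognormal daily minutes budget split into
  non-overlapping stays. Events are emitted so the debounce logic downstream
  recovers the daily values exactly: each visit is a burst of 1–5 reads
  within 10 s placed in disjoint 180-s slots; each stay emits reads every
  45 s with an exit read at the exact interval end. Reads are emitted for the
  observation week plus the first seven angling days — the two periods the
  analysis uses — and `detection_days` extends this if longer logs are
  wanted.
* **Capture.** Per one-hour session, each fish is landed independently with
  probability `logistic(a + Σ c_j z_j)` on its true z-scale traits; landed
  fish are released and stay at risk, and all landings are logged. The
  coefficient direction follows the fitted survival coefficients with signs
  flipped to the capture scale (bolder, larger, faster-growing fish more
  catchable); the intercept a = −4.7483 and overall scale 2.9827 were solved
  once (Gauss–Hermite quadrature over the latent trait distribution) so the
  expected ever-captured fraction is 0.40 at 7 days and 0.52 at 20 days.
  Hitting both targets with one hazard requires strong heterogeneity (latent
  logit SD ≈ 3.3): bold fish are caught early and the remainder are nearly
  uncatchable, which flattens the capture curve — the simulator therefore
  expresses a stronger trait–catchability coupling than a homogeneous-hazard
  model would. `calibrate_capture_intercept` re-solves the intercept for any
  other target by bisection on a fixed inner Monte-Carlo sample.
* **Landmarks.** A 16-landmark carp template is scaled by TL and deformed
  along three orthonormal shape-space directions (orthogonal to translation,
  scaling and rotation of the template): body-depth inflation scaled by the
  SB score, head aspect-ratio change scaled by SH, and a quadratic
  dorsoventral bend scaled by a per-fish standard-normal arching score; plus
  isotropic digitizing noise (default SD 0.2% of body length). The body mode
  is given twice the head mode's magnitude so the full-body PC1 identifies
  SB while the head mode still dominates the 6-landmark subset (the head
  basis is zero on trunk landmarks and vice versa). A radial head inflation
  would be absorbed by head-subset centroid scaling, hence the aspect-ratio
  choice.
* **Attrition.** 11/120 predation risk and tag loss at 15/109 among
  survivors, applied as independent end-of-experiment censoring flags (losses
  occurred mostly after angling ended), giving 94/120 ≈ 78.3% complete
  records in expectation. Attrition censors records, not behavior: lost fish
  still generated reads, but the fixture and pipeline analyze complete-record
  fish only. Predation is trait-independent (whether it correlated with
  boldness in the ponds is unknown; simulating it independent is the neutral
  choice).

What the simulator does **not** emulate: water-temperature effects on
catchability (the real experiment cooled markedly after day 7; here the
flattening capture curve is produced by hazard heterogeneity alone), hook
avoidance learning, within-day diel activity structure, close/distant spot
asymmetries beyond a noisy per-fish factor, and measurement error in TL or
growth. Passing recovery tests therefore demonstrate that the estimators
recover the generative structure of this idealized experiment, not that the
real system satisfies it.

## Determinism and problem sizes

Every `simulate_*` operation is bit-reproducible from (operation, seed) via
independent substreams, and two pipeline runs with the same seed produce
byte-identical report files (stage timings go to the logger, not the report;
every report file carries the seed in its header). The test suite runs the
gradient sign-recovery check at 500 replicate experiments of 94 fish
(~45 s) and repeatability recovery at 200 replicates via the simulator's
daily-metrics layer, which yields the same weekly means as the emitted event
stream without constructing ~10⁶ reads per replicate. The full default
pipeline (120 fish, 13 detection days, ~1.3M reads, both horizons, all nine
models each) runs in under 10 s.

## Known limitations

* The Laplace approximation with only three pond-level groups is crude; τ is
  often estimated at the boundary (0) in simulated data with no true pond
  effect. This mirrors the behavior of standard GLMM software at q = 3.
* CPUE is reported as captures ÷ (horizon × rod-hours/day × ponds); published
  CPUE figures for the original experiment do not exactly equal their printed
  counts divided by printed rod hours, so CPUE is informational only.
* Mean-standardized gradients are undefined for quadratic terms (reported as
  NaN) and uninformative for zero-mean shape scores.
* The TPS reader supports the LM/ID/SCALE dialect with 2-D landmarks only
  (no curves/outlines), which is what the digitizing workflow produces.
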