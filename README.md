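# anglesel

Quantifying angling-induced selection on fish behavior, morphology and growth.

Passively operated fishing gear (hook and line with bait) does not sample a
fish population at random: bold individuals that visit risky feeding sites
encounter baited hooks more often, larger fish may be intrinsically more
catchable, and body/head shape can affect hooking mechanics. `anglesel`
implements the full analysis chain used to measure this selection in
replicated pond experiments with PIT-tagged juvenile carp, from raw antenna
reads to mean-standardized selection gradients — together with an
individual-based simulator of the whole experiment so every stage runs and is
testable without any external data.

It is aimed at behavioral ecologists and fisheries scientists analyzing
individual capture-vulnerability experiments (PIT telemetry, mark–recapture
with binary capture fitness), and at anyone who wants a transparent,
reproducible reference implementation of the statistical machinery below.

## What it computes

**Boldness metrics and repeatability** (`anglesel.behavior`). Raw PIT reads
are debounced into feeding-spot visits and merged into shelter-presence
intervals, giving three per-fish boldness measures: visits/hr at a close and
a distant feeding spot (BP) and sheltering min/hr (SP). Consistency between
observation periods is quantified by Spearman rank correlation and by the
ANOVA-based intraclass correlation (Lessells–Boag form)

    r = s²_A / (s²_A + s²_W),   s²_A = (MS_A − MS_W) / n₀

**Geometric morphometrics** (`anglesel.morpho`). TPS landmark I/O, generalized
Procrustes superimposition (translation, unit centroid size, iterative
rotation to a consensus; reflections disallowed), Burnaby orthogonal
projection `X(I − F(FᵀF)⁻¹Fᵀ)` to remove the dorsoventral "arching" nuisance
direction of photographed fish, PCA of the projected shape coordinates
(body: 16 landmarks; head: landmarks 1, 2, 12, 13, 15, 16), and size
correction of the PC1 scores by regression on total length. The transformers
follow scikit-learn conventions (`fit`/`transform`).

**Survival models and selection gradients** (`anglesel.selection`). A fish is
assigned fitness s = 0 if first captured within the horizon (7 or 20 days of
angling), else s = 1. Nine nested logistic candidate models over the
z-standardized traits BP, TL, G, SB, SH, SP (+ BP², G²), with a pond-level
random intercept (Laplace approximation; `fixed` and `none` modes available),
are ranked by

    AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)

and Akaike weights `wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`. Coefficients of the final
model (richest within ΔAICc < 1) are linearized with the average-gradient
(Janzen–Stern) transformation

    β_SD,j = α_j · mean[Ŵ(1−Ŵ)] / W̄

which, with z-scored predictors, is the SD-standardized selection gradient,
and converted to mean-standardized gradients β_μ,j = β_SD,j · μ_j/σ_j — the
relative fitness change from doubling the trait, unit-free and comparable
across traits. Nagelkerke pseudo-R² is reported per final model.

**Pond-experiment simulator** (`anglesel.synth`). Draws a stocked population
(3 ponds × 40 fish) with the published trait correlation structure
(boldness–growth r ≈ .31, boldness–sheltering r ≈ −.52), emits PIT reads
realizing a target behavioral repeatability, runs a trait-dependent
per-session Bernoulli capture process calibrated to ≈40% captured after 7
days and ≈52% after 20, generates 16-landmark configurations with injected
body/head shape effects and an arching nuisance, and applies end-of-experiment
attrition (predation, tag loss; ≈78.3% complete records). Everything is
deterministic for a fixed seed.

## Worked example

Run the full pipeline on a simulated experiment (or point a YAML config at
your own detections/captures/traits/TPS files):

```sh
anglesel run --seed 1 --out out/
cat out/summary.txt
```

```
# anglesel 0.1.0 seed=1
fish with complete records: 99
7-day angling: 40/99 captured (40.4%), CPUE 0.476 fish/hr
20-day angling: 54/99 captured (54.5%), CPUE 0.225 fish/hr
repeatability close feeding spot: r = 0.725 (Spearman rho = 0.758)
repeatability distant feeding spot: r = 0.676 (Spearman rho = 0.728)
repeatability shelter use: r = 0.630 (Spearman rho = 0.671)
...
20-day gradients from final model #4 [BP + TL + SB + SH + G] (richest within delta-AICc < 1):
  BP: alpha = -1.496 (SE 0.44, p = 0.001), beta_SD = -0.431, beta_mu = -1.000
  TL: alpha = -1.140 (SE 0.36, p = 0.002), beta_SD = -0.328, beta_mu = -7.807
  SB: alpha = 1.094 (SE 0.35, p = 0.002), beta_SD = 0.315, beta_mu = 0.000
  SH: alpha = -1.076 (SE 0.32, p = 0.001), beta_SD = -0.310, beta_mu = -0.000
  G: alpha = -1.352 (SE 0.41, p = 0.001), beta_SD = -0.390, beta_mu = -0.622
```

Reading this: of the 99 fish with complete records, 40 were landed at least
once in the first week. Behavior is highly repeatable between the observation
week and the first angling week (intraclass correlations 0.63–0.73). In the
20-day fishery the best-supported survival model retains boldness, size,
shape and growth; the negative α for BP means bolder fish survive less, and
its mean-standardized gradient β_μ = −1.0 says doubling the visit rate costs
a fish its entire relative-survival margin. Shape scores are PCA residuals
with mean ≈ 0, so their β_μ are ≈ 0 by construction even when α is sizable.
The full tables (behavior summaries, Table-style repeatability, correlation
matrix, captured-vs-uncaught descriptives, model comparison and gradients per
horizon) are written as CSV next to the summary; two runs with the same seed
produce byte-identical reports.

Other subcommands: `anglesel simulate` (write a fixture dataset),
`anglesel behavior`, `anglesel morpho`, `anglesel select` (run single stages
on files).

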