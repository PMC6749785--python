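# Methods

`camosim` simulates, end to end, a shape-discrimination psychophysics study of
disruptive camouflage: it synthesises the stimuli (band-pass noise camouflage
with optional edge enhancement on leafy or plain backgrounds, sampled through
snake-shaped masks), runs adaptive two-alternative forced-choice (2AFC)
"wiggle"-discrimination sessions against statistical observers, fits logistic
psychometric functions to extract 75%-correct thresholds, and performs the
group-level Bayes-factor analysis. This note documents the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Viewing geometry

All sizes are specified in degrees of visual angle under a fixed calibration:
a 1,024-px stimulus subtending 29.86° viewed from 600 mm, giving a pixel
pitch of 0.3124 mm. Conversions use the full arctangent relation
`angle = 2·atan(n·pitch / 2d)` rather than small-angle scaling; with this
pitch the 82-px baseline snake width subtends 2.446° (printed elsewhere as
2.44°, a rounding difference of 0.006°) and 9.73° maps to 327 px. The two
printed pixel↔degree pairs are mutually consistent to within 0.1° under this
single pitch, which the test suite asserts. The wide-field pair (1,024 px ↔
29.86°) is taken as primary because the narrow pair inherits its print
rounding.

## Camouflage textures

Two-tone ("flat disruptive") fields are white Gaussian noise filtered in the
Fourier domain by a radial Gaussian gain `exp(−(d−μ)²/2s²)` with peak
μ = 0.07 cycles/pixel. The bandwidth parameter σ = 120 is dimensionless; we
interpret the Gaussian s.d. as `s = σ·μ` cycles **per image** (8.4/1,024 ≈
0.0082 cycles/pixel). The alternative single-unit reading (s.d. = 8.4
cycles/pixel) is flat over the whole representable band [0, 0.5] c/px and
produces structureless noise rather than camouflage patches, so it cannot be
the intended filter; both μ and σ are config-exposed. The filtered field is
posterised at its median: strictly-above-median pixels take the lighter patch
colour and ties (measure ≈ 0 on a continuous field) go to the darker one,
giving a 50/50 label split up to one pixel-row equivalent.

Patch colours are drawn from the leaf-colour pixel population: the darker
from the 35th–45th CIE L percentile band, the lighter from the 55th–65th
band. The uniform control colouration is the CIELAB midpoint of the two
patch colours, matching the mean lightness of the disruptive patterns. All
sRGB↔CIELAB conversions use the D65 2° standard observer; out-of-gamut
values are clipped on conversion.

**Edge enhancement** lightens light patches and darkens dark patches within a
band straddling every patch boundary, parameterised by the band's total
spatial width (0.63°, both sides combined) and the CIE L offset (60). Band
membership is computed from a Euclidean distance transform of the label map;
a pixel belongs to the band when its distance to the geometric patch
boundary — taken as half a pixel inside the nearest opposite-label pixel
centre — is at most half the total width. Measuring to the boundary rather
than to opposite pixel centres keeps the rasterised band width centred on
the nominal width (within one pixel either way) instead of biased a full
pixel narrow. The luminance profile across the band is a flat step of
±offset by default (a linear ramp is config-selectable); an offset of 60 L
pushes most pixels out of gamut, which is intended — the enhanced edges
saturate towards white/black.

## Leaf backgrounds

Backgrounds are fields of 4,096 leaf shapes on a 1,024² canvas. Leaf
construction is not fully specified by the study design, so the package uses
rotated ellipses (aspect ratio 1.6, rotation uniform within ±15° of
vertical) with log-normally jittered heights (relative s.d. 25%) around a
mean of 0.68°, drawn back-to-front at uniform random positions with torus
wrap-around. Each leaf's colour comes from a naturalistic CIELAB population
(L ~ N(50, 12) truncated to [20, 80], hue angle ~ N(120°, 25°), chroma ~
N(30, 8)) — the exact colours are cosmetic, but the population's broad
lightness spread is what feeds the patch-palette percentile bands.

4,096 leaves of ~23 px mean height cover only about 65% of the canvas, so
the canvas is pre-filled with an "understory" colour drawn from the same
population; the realised leaf coverage is recorded in the background's
metadata. A shadow is cast leftward of every leaf by translating the leaf
silhouette 0.15° to the left, clipping it to non-leaf pixels, and
multiplying CIE L by 0.70 (a 30% reduction) in CIELAB. Shadows are always
computed from leaf geometry and applied to the unshadowed render, so the
pass is idempotent-equivalent.

## Snake targets and scenes

The original snake silhouette is clip-art we do not have; the package's
snake is procedural: a constant-thickness tube (0.45° diameter) following a
2.5-period sinusoidal centreline over the 9.73° body height, with a rounded
head. This preserves the construct under study — horizontal rescaling
modulates curvature amplitude — and the printed dimensions. "Wiggle
amplitude" is implemented exactly as a width multiplier: the base mask is
row-wise linearly resampled (endpoint-aligned, re-binarised at 0.5) so its
occupied extent is `round(amplitude × 82)` px at every amplitude in
[0.3, 2.5], with the vertical extent fixed at 327 px and mask area scaling
linearly within 2%.

Scenes place two snakes side by side. The printed eccentricity of "15.9°
from the centre" cannot be a per-snake offset (it maps to 543 px, beyond the
512-px half extent), so it is read as the centre-to-centre separation
(±7.95°), config-overridable. Each snake gets an independent uniform
vertical offset in ±1.49°, an independently drawn texture instance (from ten
pre-generated per colouration), and on leafy trials one of ten pre-generated
backgrounds; the target side is random. Scene rendering is optional during
simulated sessions: the statistical observer consumes amplitudes, not
pixels, and every trial record carries the full scene parameters needed to
re-render it.

## Simulated observers

An observer's probability of picking the more-wiggly snake depends only on
the unsigned amplitude difference Δ = |target − foil|:

    p(Δ) = 0.5 + (0.5 − λ) / (1 + exp(−k(Δ − Δ*)))

with guess rate 0.5 (2AFC chance), lapse λ (default 0.02, capped at 0.06),
slope k (cohort mean 25 per amplitude unit, s.d. 5) and per-condition true
threshold Δ* (the 75% point when λ = 0). The shared pedestal cancels in Δ,
so the default observer is pedestal-invariant — the pedestal exists to block
absolute-magnitude strategies in humans, which a statistical observer has no
analogue of; a Weber-like pedestal-sensitive variant is switchable for
robustness experiments. At Δ = 0 "correct" is undefined and is scored as a
fair coin.

Cohorts (default n = 26) draw each observer's condition thresholds as
condition means + a shared observer offset (s.d. 0.03) + independent
condition noise (s.d. 0.02), truncated at 0.02. The default condition means
are ordered uniform < flat disruptive < edge-enhanced disruptive on both
backgrounds (leaf: 0.10 / 0.14 / 0.20; grey: 0.09 / 0.11 / 0.16). These
effect sizes are this package's choices for demonstrating that the pipeline
can detect an ordered pattern; they are not measured values, and passing the
end-to-end checks shows the pipeline's sensitivity at these effect sizes,
not anything about real observers. The generator also omits every
image-level influence on behaviour (no pixel-computable decision model),
learning/fatigue, and response-time structure.

## Staircase design

Two staircases per condition start at amplitudes 1.2 and 0.8 and adapt the
unsigned distance δ = |level − 1| by a 3-down-1-up rule: three consecutive
correct responses shrink δ by one step, any error grows it. The rule is
inferred from the printed convergence point — the balance condition p³ = ½
gives p = 0.5^{1/3} = 79.37% correct. The step schedule (start 0.05, halved
at the first two reversals, minimum 0.0125) is not specified by the study
and was chosen so a 30-trial staircase starting at δ = 0.2 can reach and
bracket plausible thresholds. δ is floored at the minimum step (a staircase
crossing baseline would invert the correct-response mapping) and levels are
clamped to [0.3, 2.5]. Sessions interleave all 12 staircases by uniform
random selection among the unterminated ones, draw a shared pedestal from
{−0.20, …, +0.20} in 0.05 steps each trial, and produce exactly 360 records.
Session randomness is split into four independent substreams (interleaving,
pedestals, sides, responses) spawned from one seed.

The long-run equilibrium is verified empirically by `simulate_convergence`:
a 100,000-trial constant-step track against an observer with a known p(Δ).
The mean level of a finite-step up-down track sits slightly above the
balance point (the track dwells asymmetrically around it), so the asymptote
is measured with a 0.005 step — finer than the session minimum — which
brings the systematic offset well inside the ±0.5 percentage-point check.

## Psychometric fitting

Each condition's 60 trials are folded onto Δ, proportions correct are pooled
per distinct level, and a logistic with fixed asymptotes (γ = 0.5, λ = 0) is
fitted by least squares weighted by trials per level. With the asymptotes
fixed, ψ(α) = 0.75 identically, so α is the 75% point and the reported
threshold is 1 + α. Folding is the only convention under which a single
increasing logistic is well-defined across both staircases. The pedestal is
excluded from Δ (it cancels by construction). Optimisation is a 30×20
(α, β) grid scan followed by bounded L-BFGS-B from the best grid point plus
one fixed start, α ∈ [0.005, 0.6], β ∈ [1, 200]; fits with α stuck at a
bound (e.g. all-correct data) are flagged, not silently reported, and
flagged cells propagate as missing into the group table. The generative
lapse of 0.02 biases the fitted α upward by ≈0.003 (the fit's λ is fixed at
0), negligible against the ±0.03 recovery check.

## Bayes factors

Paired and one-sample t tests use the default Jeffreys–Zellner–Siow setup: a
point null against a Cauchy(0, r) prior on the standardised effect with
r = √2/2 (the default of common Bayesian-statistics software; config
exposed). BF10 is the ratio of the marginal likelihood of the observed t —
the noncentral-t density integrated against the Cauchy prior, by adaptive
quadrature at 1e-10 relative tolerance — to the central-t density. The test
suite checks this against an independently coded dense-grid trapezoid
integration and against `pingouin.bayesfactor_ttest` to better than four
significant figures. The one-sided variant folds the prior to positive
effects. Zero-variance differences raise a degenerate-data error (t is
undefined there). Evidence labels follow the conventional ladder — (1, 3]
anecdotal, (3, 10] moderate, (10, 30] strong, (30, 100] very strong, > 100
extreme, mirrored in reciprocals for H0; the classifier follows the scheme's
boundaries even where a source text labels a value loosely. Group condition
means carry 95% percentile bootstrap CIs over participants (default 10,000
resamples). No multiplicity adjustment is applied.

The two-way Bayesian ANOVA model comparison is out of scope; the pairwise
and one-sample tests carry the analysis surface.

## Numerical and reproducibility choices

* One master seed drives everything; stage and per-texture/per-session
  substreams are spawned via `numpy.random.SeedSequence`, so any single
  trial can be re-simulated in isolation.
* Median ties in posterisation go to the dark label (deterministic).
* Image coordinates are 0-based, row-major, origin top-left, y downward.
* Degenerate inputs fail loudly: constant filtered fields, identical colour
  populations, uniform textures passed to edge enhancement, zero-variance
  difference vectors, and sub-minimum trial counts all raise typed errors.
* Problem sizes in the test suite are scaled to keep the default run fast:
  unit tests use 256–512 px textures/backgrounds and ~30-session recovery
  checks, while the acceptance-style tests use the full 1,024-px, 4,096-leaf,
  200-session and 100-study sizes.

## Known limitations

* The snake silhouette, leaf outlines, and leaf colour population are
  plausible stand-ins, not the original art or colour sample; every quantity
  the tests assert is independent of those cosmetic choices.
* The observer model is not image-computable: condition difficulty is
  injected through Δ*, so the pipeline cannot discover camouflage effects
  from pixels — it validates the measurement and inference chain around
  them.
* Per-fit confidence intervals are not provided (group bootstrap only).
* Reported thresholds assume the folded-difference convention; signed-level
  fitting is not implemented.
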