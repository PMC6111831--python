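# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, what the synthetic stimuli do and do not
probe, and the limitations we know about. Every empirical statement here
is computed by the test suite or by `scripts/acceptance.py`.

## Model overview and assumptions

The detector is a feedforward cascade with one lateral (surround) and
one feedback interaction, mirroring the early visual pathway:

    RGB → retina/LGN opponency → V1 filter bank → V2 pooling (+feedback)
        → NCRF surround inhibition under two-scale guidance → contour map

All processing is static (no temporal dynamics), all fields are
non-negative after each rectification, and the whole pipeline is
deterministic: two runs on the same input are bit-identical, which the
tests assert.

Conventions shared by every stage: row-major arrays, origin top-left,
`x` along columns, `y` along rows, angles from the +x axis toward +y;
filtering is correlation (kernels are not flipped — every kernel used is
either point-symmetric or generated per orientation over the full
circle, which makes the distinction immaterial for the bank); borders
are reflect-padded so constant images are fixed points of smoothing;
kernels are truncated at three standard deviations and renormalised.

## Stage by stage

### Retina and LGN (single opponency)

Retina and ganglion/LGN receptive fields are merged into one layer. The
opponent drives are

    U_rg = I_r ∗ G(σ) + w · I_g ∗ G(σ)
    U_by = I_b ∗ G(σ) + w · I_y ∗ G(σ),   I_y = (I_r + I_g)/2

with one antagonist weight `w ∈ [−1, 0]` shared by both axes (no
channel-specific value exists to distinguish them). Firing rates are
non-negative, so each signed drive is split into an on/off pair:
`rg = ⌊U_rg⌋`, `gr = ⌊−U_rg⌋`, and likewise by/yb. At `w = −1`
achromatic input cancels exactly; at the default `w = −0.8` a uniform
achromatic field leaves a constant opponent residual, which the next
stage's zero-mean filters remove.

Single-opponent responses are spatially low-pass: they fill regions, not
edges. A red/green half-field drives `rg` across the whole red half.
Edge localisation first appears at V1 — this matters when interpreting
the isoluminant-edge probes.

### V1 (double opponency, complex cells, normalisation)

The simple-cell kernel is the first derivative along its preferred
direction θ of an anisotropic Gaussian (aspect λ = 0.5, width kσ,
defaults k = 2, σ = 1.1). It has exactly zero mean on the symmetric
grid, and θ + π gives the opposite polarity.

The double-opponent wiring feeds the kernel's on-subfield with the
on-centre opponent input and the off-subfield with the off-centre input.
Because the pair is a rectified decomposition of one signed field, this
is the signed filtering

    E_co(θ) = ⌊(S_co − S_co′) ∗ V(θ)⌋,

with the opposite polarity appearing in the θ + π slice. We considered
the alternative of applying the two rectified kernel lobes as separate
non-negative filters and summing; it is rejected because it adds a DC
pedestal proportional to the local opponent mean — on a textured test
image the final edge map then spans only [0.73, 1.0] (no contrast), and
a structureless "white wall" saturates to ≈ 1, defeating the very
normalisation floor introduced to keep such regions silent. The signed
reading restores zero response on constant input at any `w`.

Complex cells take the pointwise MAX over the N = 6 orientation slices.
One consequence worth knowing: with orientations covering the full
circle, the MAX over θ makes each on/off channel pair identical
(`Ẽ_gr ≡ Ẽ_rg`), and on grey images the r-g and b-y channels coincide
too. The four-channel bookkeeping is kept for fidelity to the wiring,
but on achromatic input the channel sum and the channel max are
proportional.

Self-normalisation `D = Ẽ²/(max Ẽ² + ε)` (global maximum per channel
per scale, ε = 1e−8) bounds responses to [0, 1), is scale-invariant up
to ε, and passes all-zero fields through untouched. The strict bound
holds for everything the cascade produces from [0, 1] imagery; for
artificial fields with magnitudes ≳ 1e4 the ε term falls below float64
resolution and the bound saturates to 1.0 exactly.

### V2 (elliptical pooling, one-shot feedback)

Each channel's normalised field is pooled with an elliptical Gaussian
whose short axis (σ) lies along the per-pixel dominant edge normal — the
argmax direction of the channel's simple-cell stack — and whose long
axis (σ′, default 2σ, exposed as a parameter) lies along the tangent.
Implementation: pixels are quantised into the N orientation classes and
each class is filled from its own masked convolution. The printed
cross-term form of the ellipse's quadratic is dimensionally inconsistent
in one coefficient; the standard rotated-Gaussian sum form is used (the
two agree at axis-aligned angles), and a `printed_form` flag retains the
literal variant so the discrepancy is demonstrable.

The edge map is `D = Σ_c V2_c + max_c V2_c`: feedforward sum plus a
feedback term applied exactly once, taken per pixel. The map is then
rescaled by its global maximum so the two scales of the hierarchy are
comparable; a numerical-noise guard (peak ≤ 1e−12 → exact zeros) keeps
white-wall inputs silent through the rescale.

### Surround inhibition and multi-scale integration

Four cues modulate an annular surround, 2–5× the CRF diameter:

- **Distance** `W_d`: rectified difference of normalised Gaussians
  ⌊G(ρσ) − G(σ)⌋, L1-normalised; zero at the centre, a ring peaking a
  few pixels out, then monotone decay. ρ defaults to 4. The printed
  value 0.4 would make the "surround" a centre blob and contradicts the
  2–5× anatomy, but remains reachable via `dog_plus_kernel(strict=True)`.
- **Luminance and contrast similarity** `W_L`, `W_C`: local statistics
  L and C are computed under an 11×11 raised-cosine window
  (`(cos(πr/R)+1)/2`, R = 6) from the greyscale projection
  0.299 R + 0.587 G + 0.114 B; C's denominator L² is floored at 1e−4 in
  dark regions; both are min-max rescaled to [0, 1] (a constant field
  maps to zero by convention). The weights are W_d-weighted convex sums
  of Gaussian similarities `exp(−ΔL²/2σ₁²)` with σ₁ = 0.05 shared by
  both cues, so uniform inputs give exactly 1. A nested-loop oracle
  reproduces the vectorised implementation to 1e−6.
- **Colour-orientation similarity** `W_θ`: the per-orientation colour
  responses (channel-max of the simple-cell stacks, put on a [0, 1]
  footing by one global rescale so the difference lives on σ₂'s scale)
  are averaged under G(σ) at the centre and under W_d in the surround;
  Δθ is the Euclidean norm of the N-vector of differences and
  `W_θ = exp(−Δθ²/2σ₂²)`, σ₂ = 0.2. Uniform texture ⇒ Δθ = 0 ⇒ maximal
  suppression weight.

The two-scale guidance runs the complete cascade at σ and 2σ (each map
max-normalised) and uses the sign of ΔD = D(2σ) − D(σ): where ΔD ≥ 0
the strongest of the three weights applies (texture — suppress hard),
elsewhere the weakest (contour — suppress gently). The direction of
this convention was settled empirically: with per-scale normalisation,
the blurred coarse map fills the gaps between texture elements and
exceeds the sparse fine map at ~95% of texture-interior pixels on the
textured-square stimulus, while salient contours keep fine-scale peaks.
ΔD is not smoothed before the sign test. Surround weights are computed
once, at the fine scale.

The final response is `CD = ⌊D(σ) − α·W·(D(σ) ∗ W_d)⌋` with the texture
attenuation factor α = 1 (one of the model's two tuned free parameters,
the other being w = −0.8). CD is pointwise non-increasing in α and never
exceeds the fine-scale map.

### Post-processing and evaluation

Non-maxima suppression keeps a pixel iff it is ≥ both neighbours along
its quantised (8-connectivity) edge normal — taken from an orientation
stack when available, else from the Sobel gradient of the response.
Ties survive, so ideal one-pixel ridges pass unchanged and plateaus are
left for hysteresis. Hysteresis seeds at the (1−p)-quantile of positive
values, extends through 8-connected pixels above `0.4 × high` (both
knobs exposed), and is monotone in p. The NMS-only map is the default
evaluation input; binarisation is opt-in.

Evaluation matches predicted and ground-truth pixels one-to-one,
nearest pair first, within a Euclidean tolerance (default 0.0075× the
image diagonal, exposed in config). Greedy nearest-first matching
approximates the classical min-cost assignment; on fixtures without
dense parallel structure the two coincide. P-R curves sweep levels
spaced relative to the response's own maximum (so maps with different
dynamic ranges are compared fairly), thin once, and report the
trapezoidal area under P(R) and the best F over levels. The consensus of
several annotator masks is binarised at 0.5 (majority).

## Synthetic stimuli

The generator produces five parametric classes, each a pure function of
its spec (same spec ⇒ bit-identical image and ground truth):

- **grating** — achromatic sinusoid, the orientation-tuning probe;
  ground truth empty (pure texture). Coordinates are centred so the
  central pixel sits at maximal gradient.
- **textured_square** — oriented-bar texture θ_in inside a centred
  square, θ_out outside; ground truth is the 1-px perimeter. Bars are
  anti-aliased segments (length 7 px, coverage 8%, amplitude ±0.25 on
  mid-grey) on a jittered grid — the standard construction for
  orientation-contrast stimuli, chosen because it keeps first- and
  second-order luminance statistics equal across the boundary (within
  2% at 96×96), so the perimeter is defined by orientation alone.
- **isoluminant_edge** — two colours rescaled to equal greyscale
  luminance (to 1e−6); a purely chromatic vertical boundary.
- **two_tone_edge** — an achromatic luminance step.
- **cluttered_scene** — 2–4 textured or isoluminant-colour rectangles
  on a textured background; ground truth is the union of perimeters.

What passing on these stimuli shows — and what it does not: the
fixtures verify orientation selectivity, chromatic-boundary detection,
suppression geography and the end-to-end plumbing, but they are
parametric, not natural. They lack 1/f statistics, shading, occlusion
and the point-like noise clutter of photographs, so fixture scores say
nothing quantitative about natural-image benchmarks.

## Study conditions for the ablation comparison

The ablation experiment compares the full model against `no_v2` (stop at
V1), `no_feedback` (drop the channel-max term), `no_multiscale` (apply
the max-weight branch everywhere) and the raw fine-scale map, on
textured squares and cluttered scenes at 96×96 (seeds 0–2, six fixtures).
Scoring is the dataset-level best F (counts aggregated across fixtures
per threshold, as boundary benchmarks do) with a 3.5-px matching
tolerance — half the texture element length, since a texture-defined
boundary cannot be localised finer than its element — over 30 levels.

Measured outcome (recomputed by `scripts/acceptance.py`): the full model
beats the raw fine-scale map and the no-multiscale variant, confirming
that the guided surround inhibition earns its keep. The V2 pooling and
feedback stages, however, are neutral to marginally negative (≤ 5%
relative) on these stimuli: feedback is provably inert on achromatic
content (after MAX pooling over the full circle the on/off channels
coincide, and on grey input the two colour axes coincide too), and the
2:1 elliptical pooling trades localisation for collinear integration —
a trade that pays on natural images with noisy point clutter and strong
global shape, not on parametric bar textures. The corresponding
ordering assertions are stated strictly in the acceptance tests and are
expected to fail at this margin; we report this rather than weaken the
test.

## Numerical choices

- Kernel truncation at 3σ with renormalisation; V1 kernel support is
  sized to the kσ axis (side 2⌈3kσ⌉+1); the λ-elongated axis is clipped
  at 1.5 of its standard deviation, which preserves the exact zero-mean
  antisymmetry.
- ε = 1e−8 (normalisation floor); 1e−12 (global-rescale noise floor);
  1e−4 (contrast denominator floor); all orders of magnitude away from
  genuine signal levels on [0, 1] imagery.
- Min-max rescale of a constant field is defined as the zero field.
- The ΔD = 0 tie takes the max (texture) branch.
- NMS ties survive (≥ comparison); hysteresis uses ≥ thresholds so the
  p → 1 limit keeps every positive pixel.
- Greedy matching sorts candidate pairs by distance with a stable sort,
  making the evaluation deterministic.

## Limitations

- Single fixed fine scale (σ = 1.1): no scale-space search; very thick
  or very blurred boundaries respond sub-optimally.
- The V2 stage models only the elongated ("slender") receptive-field
  class; multi-orientation V2 structure, V4 and motion feedback are out
  of scope.
- Feedback is one-shot; no recurrent settling.
- Suppression-geography statistics on texture fixtures are seed-dependent
  at 64×64 (the surround annulus spans only a few texture elements);
  96×96 is the smallest canvas at which they stabilise.
- The BSDS-style harness (image + multi-annotator masks by filename
  stem) is provided, but no natural-image scores are claimed here.
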