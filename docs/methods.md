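# Methods

This note documents the models, conventions and design choices behind
`destreak`, and what the shipped synthetic experiments do and do not
show.

## Coordinate and geometry conventions

Images are square grids over the field of view `[-1, 1]²` with pixel
centres at `(-1 + (i + 0.5)·px)` for `px = 2/N`; attenuation values are
per unit length in those coordinates, so line integrals are
dimensionless. Parallel-beam geometry: view angles
`θ_v = v·span/n_views` degrees (half-open, no repeated endpoint), ray
set `{x cosθ + y sinθ = s}` with detector offsets
`s_d = (d − (n_detectors−1)/2 + offset)·spacing`. The shipped default —
1200 views over 360°, `1.5N` detectors (rounded up to even) at one
pixel of spacing — keeps the detector array wider than the field-of-view
diagonal. The pseudo-projection geometry is deliberately independent of
whatever produced the input image; doubling the view count to 2400
changes the pipeline output by well under 1% relative RMSE.

## Phantoms

Phantoms are sums of ellipses with additive attenuations, rasterized by
centre-of-pixel point sampling (no anti-aliasing): the rasterizer stays
trivially testable, and the *analytic* ellipse sinogram — exact chord
lengths from the quadratic ray/ellipse intersection — serves as the
projector's oracle, not the raster. The `torso` preset is a 0.9 × 0.55
body ellipse (attenuation 2.5), two dense shoulder disks (radius 0.18
at x = ±0.62, +4.0) and four small interior features (contrast ±0.6 to
+1.0, including a 0.04-radius dense "spine" marker used for FWHM
probes). The widest shoulder-to-shoulder ray integrates to ≈ 7.4, so at
the default low dose the transmitted mean is < 1 photon — genuine
starvation along exactly the direction the artifact model predicts;
the widest vertical ray integrates to ≈ 3.5.

## Forward projector

Joseph-style ray-driven integration: each ray is sampled at uniform
steps of half a pixel, the image is bilinearly interpolated (zero
outside the grid), and the bin value is the step-weighted sum. The
projector is linear, preserves non-negativity, and `forward_project`
bins equal `ray_integral` at the same ray bitwise. Against the
closed-form ellipse sinogram of the torso preset (N = 256, 1200 views)
the agreement is ~1% for 99% of bins; the *maximum* deviation, ~2.6% of
the sinogram peak, sits on rays tangent to ellipse boundaries, where
any N = 256 raster carries an `O(μ√(R·px))` representation error (R the
boundary's curvature radius). That tangent-ray floor halves at N = 512;
it is a property of discretizing a discontinuous object, not of the
integrator, whose own step error is ~0.002%.

## Low-dose noise model

Transmitted counts are independent Poisson draws with mean `I0·e^(−p)`;
the post-log measurement is `ln I0 − ln max(counts, clamp)` with
`clamp = max(starvation_floor, 1)`, so starved bins saturate at
`ln I0` instead of diverging (clamping at one count is the standard
convention; the floor is configurable). `I0` is treated as a noiseless
constant. First-order propagation gives `var(p) ≈ e^p / I0`, the
exponential variance law that motivates thresholding on the projection
value; Monte-Carlo variance matches it within 5% for p ≤ 3 and
I0 ≥ 10³ (the exact clamped variance at p = 3, I0 = 10³ is ~3% above
the first-order value — the approximation, not the simulator, is the
limit). Shipped doses: I0 = 10³ (low) and 2·10⁴ (regular). Not
modelled: electronic/readout noise, beam hardening, scatter, detector
crosstalk, bowtie filtration.

## FBP

The ramp filter is built in the frequency domain as the exact DFT of
the band-limited spatial Ram-Lak kernel (`1/(4ds²)` at zero,
`−1/(π²k²ds²)` at odd lags), avoiding the DC bias of naive `|f|`
sampling; rows are zero-padded to `pad_factor ×` the next power of two
(default 2) against circular wrap. The interior response to a constant
row is < 10⁻³ of the input (in detector-bin units); the row ends react
to the implicit step down to the padding, as any finite-support ramp
must. Backprojection is pixel-driven with linear interpolation between
detector bins, weighted `Δθ = span/n_views` with a global 1/2 for 360°
spans (each ray measured twice). Optional Hanning apodization
multiplies the ramp by `0.5 + 0.5 cos(πf/f_Nyq)` — the shift-invariant
smooth-FBP comparator; the pipeline default is no apodization, since
artifact reduction, not denoising, is the goal. Numerically: the
analytic disk sinogram reconstructs its interior mean to 0.01%, and the
projector→FBP round trip on the torso stays within ~4.5% relative RMSE
on the body (dominated by interpolation blur and Gibbs ringing at the
dense shoulder edges).

## The shift-variant filter

`T = fraction × global max` of the pseudo sinogram, computed once per
call; the default fraction 0.75 and the 13-tap kernel are the published
working point. Each row's moving average is computed once from the
*original* row and spliced in where `p ≥ T` (non-recursive
substitution — order-independent, unlike an in-place loop; bins exactly
equal to T are filtered). Boundary handling is `reflect` (mirror
including the edge sample; `replicate` available), chosen to avoid
dimming high-attenuation bins near row ends. Filtering is strictly 1D
along detectors, never across views. Consequences verified in the
suite: positive homogeneity (`T` scales with the data), nonlinearity
and shift variance, sparsity of intervention (~2.6% of bins on the
shipped experiment), and contraction under re-application.

## Evaluation metrics

* **SSD** `= Σ(X_gold − X)² / (√ΣX_gold² · √ΣX²)`. The denominator is
  this package's convention, chosen as the product of norms so the
  quantity is dimensionless and symmetric.
* **NPS image** `= |FFT2(X_gold − X)|`, centred. Horizontal streaks
  concentrate energy along the central *vertical* frequency axis;
  `central_vertical_band_energy` sums `|NPS|²` over `|f_x| < 3` bins.
* **MTF image** `= (|FT(X_out)| + ε)/(|FT(X_in)| + ε)`, ε = 0.1. Wedge
  curves average the polar-resampled image (1-pixel radial × 1° angular
  steps, bilinear) over ±16° wedges about 0°, 45°, 90°, each paired
  with its point reflection (Hermitian symmetry), then normalize to 1
  at zero frequency — averaging plus normalization rather than a raw
  sum, so curves are comparable across images.
* **FWHM** of a line profile: baseline = profile minimum, crossings at
  half-rise located by linear interpolation; affine-invariant.

## The shipped experiment and the dose regime

One seed drives the whole comparison: gold = regular-dose FBP of the
analytic torso sinogram; raw low-dose FBP (B); the proposed pipeline
applied to B via pseudo projections (C); Hanning-FBP of the same
unfiltered pseudo sinogram (D); and the selective filter applied
directly to the measured low-dose sinogram (C′). Per-stream seeds
derive from the master seed; identical seeds give bit-identical
outputs.

Across ten seeds, C beats B on SSD by ~3× and beats C′ (re-projection
itself low-passes some noise away), the NPS vertical-band energy drops,
and the filter touches ~2.6% of bins. Two behaviours differ from the
clinical regime the method targets, and both trace to the same cause:
at I0 = 10³ *every* detector bin — not just starved ones — carries
percent-level post-log noise (`var ≥ 1/I0`), so image error is
dominated by broadband noise rather than streaks. First, the globally
smoothing comparator D attains a lower SSD than C at this scale: it
halves the ubiquitous noise everywhere at a modest blur cost on a
piecewise-constant phantom, an advantage that vanishes when non-starved
rays get the 10⁴–10⁶ effective photons of a clinical scan. Second, the
SSD-vs-threshold curve is not flat here (~40% variation over fractions
0.65–0.85): lowering T keeps paying because the extra smoothed bins are
themselves noisy, whereas in a photon-rich regime bins below the
starved set are clean and the curve plateaus. Passing the shipped tests
therefore demonstrates the mechanics and the artifact-targeting of the
method, not SSD superiority over global apodization at arbitrarily low
flux.

## Problem sizes

The shipped experiment runs at N = 256 with 1200 views (the published
view count) — small enough that a full ten-seed evaluation, the
threshold sweep and a 2400-view comparison complete in a few minutes on
one CPU; unit tests use N = 64–128 with proportionally fewer views.

## Known limitations

2D parallel-beam only (no fan/cone beam); ellipse phantoms lack
anatomical texture, which makes smoothing comparators look better on
SSD than they would on real anatomy; the threshold rule is the fixed
fractional one (no automatic selection); FWHM requires a single-peaked
profile and refuses flat or boundary-peaked input.
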