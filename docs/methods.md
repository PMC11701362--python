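# Methods

This note records the models, conventions and numerical choices behind
`wellkinetics`, including every decision the underlying method leaves open.

## Colour model

Pixels are assumed to be 8-bit sRGB as consumer cameras emit them; no
colour management, white-balance correction or chart calibration is
applied. The conversion chain is sRGB → linear RGB (IEC 61966-2-1
decoding) → CIE XYZ (the classic 6-decimal sRGB matrix, D65 illuminant,
2° observer, reference white X=0.95047, Y=1, Z=1.08883) → CIE 1976
L\*a\*b\* with the exact rational constants (breakpoint δ = 6/29). The
conversion is implemented in-package rather than delegated: widely used
library routines carry the truncated `7.787` constant in the Lab
f-function, which perturbs dark colours at the ~1e-4 level, and the test
suite holds this implementation to 1e-6 agreement with independently
hand-coded CIE formulas (the library routine remains a cross-check at its
own accuracy).

ΔE is the CIE76 Euclidean distance. The more elaborate CIE94/CIEDE2000
variants are deliberately out of scope: the quantity tracked here is a
*magnitude of change over time within one well*, for which the plain
metric is the transparent choice.

**Averaging order.** An ROI is reduced to its arithmetic mean in RGB and
the mean is then converted to Lab/HSV. Converting per pixel first and
averaging in Lab is available as an option (`per_pixel_conversion`); for
the near-uniform wells this pipeline targets the two differ negligibly,
and RGB-first averaging keeps the reported RGB/Lab/HSV triples mutually
consistent. Channels stay real-valued after averaging — no
re-quantisation.

## ROI geometry

Grids of circular ROIs are specified numerically (rows × columns, centre
of the first well, pitches, one common diameter) — the scriptable
equivalent of GUI well-picking. Conventions, fixed so that results are
bit-exact and testable: 0-based (row, col) pixel coordinates, origin
top-left; pixel centres at integer coordinates; membership is Euclidean
distance to the ROI centre **≤ radius** (boundary inclusive); labels run
row-major A1, A2, … Whether a boundary pixel is in or out is a convention,
not science — inclusive was chosen and is frozen by the brute-force
equivalence tests. Disks that would leave the frame are an error naming
the offending well; overlapping disks are detectable (`masks_overlap`)
and rejected by the synthetic renderer.

## Kinetic read-outs

All read-outs operate on the per-well series ΔE(t) versus the well's own
first frame (reference frame configurable by index; cross-well references
are unsupported by design — each well is its own control).

- **Smoothing**: centred moving average, default window 25 frames (1 s at
  25 fps), window shrinking symmetrically at the edges so affine series
  pass through unchanged. Applied before any differentiation. For noisy
  video (per-pixel σ of several counts) a much wider window is the right
  analysis — the robustness tests use 60 s — because the variance of the
  differentiated signal scales inversely with the smoothing span.
- **Gradient**: central differences in the interior, one-sided at the
  ends (exact for quadratics), in ΔE per *second*, matching the threshold
  units.
- **Endpoint**: the profile must first *activate* (smoothed gradient ≥
  threshold somewhere); the endpoint is the earliest later time at which
  the gradient drops below the threshold (default 0.05 ΔE·s⁻¹) and stays
  below it for a persistence window (default 10 s) of recorded data.
  Without activation, a flat pre-reaction trace would "end" at t = 0;
  without persistence, one noisy dip would end it mid-rise. Both guards
  are configurable; a well that never activates or never settles reports
  no endpoint (empty CSV cell, JSON null).
- **Induction time**: the time of maximum |smoothed gradient| of a chosen
  channel (default ΔE; a\* is the natural choice for green→red
  chemistry). A first-threshold-crossing definition is available as
  `method="threshold"`. The magnitude is used so falling channels (e.g. a
  decaying L\*) are handled identically.
- **AUC**: trapezoidal integral of ΔE over the full recording — the
  sedimentation grade (slower settling / more suspended solid ⇒ larger
  area).

## Synthetic plates and what they do (not) show

The generator renders circular wells on a uniform background. Each well
interpolates linearly in RGB between a start and an end colour under a
monotone mixing function: exponential decay (rate k, optional lag),
logistic (steepness s, midpoint t_mid), step, constant, or
amplitude-scaled exponential settling ("turbidity clearance", AUC ∝
amplitude). Optional per-pixel i.i.d. Gaussian noise and a saturated white
glare disk are added; a seed fixes all randomness bit-exactly. The
companion `analytic_summary` pushes the same noiseless trajectory through
the colour pipeline on a 10× denser time grid and applies the *same*
activation/persistence endpoint rule to the continuous curve, so detector
and oracle differ only by measurement effects.

Default study conditions used by the recovery tests, chosen to mirror the
emulated chemistries: a 4×6 (24-well) plate at 25 fps for 600 s, twelve
dye-decay wells with rates 0.008–0.03 s⁻¹ (endpoints spread over
~130–320 s) and twelve sigmoidal wells (s = 0.05 s⁻¹, midpoints
80–300 s), purple (110, 45, 150) clearing towards the background
(215, 215, 210). Induction tests use steeper logistic wells (s = 1 s⁻¹, a
colour transition spanning a few seconds) along a blue–yellow axis pair
chosen because its RGB→Lab arc is nearly linear: the argmax of d(ΔE)/dt
shifts from the logistic midpoint by ≈ (f″/f′)/(2s), where f is the
arc-length nonlinearity, so a near-linear pair keeps the shift below the
stated ±2-frame tolerance. These numbers were derived from that analysis,
not fitted to test outcomes.

**Quantisation.** Rendered channels are rounded to 8-bit by default
(±half-count error, ≤ ~1 ΔE after conversion). Rounding has a structural
consequence for endpoint precision: near a gradient threshold θ the
quantised ΔE staircase steps by one quantum q every ~q/θ seconds
(~6–10 s at θ = 0.05), independent of the reaction rate, so *no* detector
can localise the crossing to a couple of frames from 8-bit data of a
noise-free uniform well. The renderer therefore supports
`quantise="none"` (continuous channels); frame-accurate recovery claims
are made under that policy, while the quantised case is bounded at its
honest tolerance (≈ persistence + two staircase steps) in a separate
test. Ironically, sensor noise *helps*: with hundreds of pixels per well,
per-pixel noise dithers the rounding and the ROI mean becomes
near-continuous again — the noisy recovery tests use rounded frames.

Synthetic plates do not emulate: spatial lighting gradients, parallax,
lens blur, background drift, camera compression artefacts, shadows or
meniscus effects. Passing recovery tests therefore demonstrates the
correctness of the *algorithms*, not robustness to every real optical
artefact; glare, the one optical artefact modelled, is injected as a
saturated disk.

## Glare dispersion

Per-pixel conversion of one ROI in one frame to Lab, scattered in the
(L\*, b\*) plane; the report's scalar is the RMS Euclidean distance of the
points from their centroid. "Tightness" of such scatter plots is
otherwise qualitative; the RMS definition is this package's own,
deliberately restricted to the L\*–b\* plane (a\* excluded) to match the
plane being plotted. It is zero iff all pixels coincide, invariant to
pixel order and duplication, and never increased by adding a pixel at the
centroid.

## Mutual-information channel ranking

Offline assays (HPLC conversion) yield 5–15 points; video yields
thousands. Colour channels are linearly interpolated onto the assay times
(never the reverse — the sparse series dictates the support; queries
outside the recorded span are errors, not extrapolations). MI between an
aligned channel and the assay values is estimated by the plug-in formula
on an equal-frequency (quantile) joint histogram with ⌈√n⌉ bins per
variable, computed from mid-ranks, reported in nats and clamped at zero.
Rationale: at these sample sizes k-NN estimators are fragile, while
rank-based binning is exactly invariant under any strictly *increasing*
transform of either variable — the "no linearity assumed" property that
motivates MI here. (Under *decreasing* transforms the invariance is exact
precisely when the bin count divides n, since the reversed equal-frequency
partition must coincide with the original; this is a property of every
equal-frequency estimator, not an implementation artefact.) Scores are
normalised by the channel maximum, so the best channel scores 1 and ties
break alphabetically; if every channel is constant the ranking is all
zeros rather than an error. The estimator sits behind a single function
and can be swapped.

The linear ΔE–conversion fit is closed-form OLS with the convention
r² = 0 (slope 0) for a constant response and an error for constant x.

## Determinism and I/O

Timestamps are index/fps exactly; image sequences require an explicit
frame rate; variable-frame-rate containers are rejected rather than
resampled (every read-out assumes uniform sampling). Trace CSVs are
written with `%.10g` so a read-back reproduces values to better than 6
significant figures; identical configuration and input produce
byte-identical CSVs (verified by checksum in the tests). Video containers
are read through imageio when a suitable codec backend is present; PNG
image sequences are the fully deterministic reference path and are what
the synthetic generator writes.

## Problem sizes

The test suite and the acceptance script run everything at the sizes
stated above (the 24-well 600 s plate is the largest single computation,
~15,000 frames); MI ranking uses 100 seeded replicates of a 16-point
assay; noise robustness uses 20 seeds × 2 wells at 10 fps. Larger inputs
are generated at run time by the same code paths.

## Known limitations

- Endpoints, induction times and AUC are descriptive read-outs; no rate
  law is fitted and no rate constant is reported.
- The plateau rule depends on threshold, smoothing and persistence; the
  defaults (0.05 ΔE·s⁻¹, 25 frames, 10 s) are sensible for 25 fps video
  of minute-scale chemistry but are not universal — `print-config`
  exposes all of them.
- ROI selection is manual by design; automated well detection is out of
  scope.
- Colour quantities are camera-relative: without calibration, ΔE values
  are comparable within a video, not across instruments.
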