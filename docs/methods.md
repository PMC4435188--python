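# Methods

## Detection model

The detector treats a nest as a small region that (a) visually stands out
from a homogeneous row-crop field and (b) does not match the field's
appearance statistics. Both cues are computed per frame and fused; neither
alone is reliable — saliency also fires on shadows, machinery and bright
soil patches, while the appearance test also fires on distribution tails —
but their conjunction, followed by blob-size filtering and a temporal
consistency check, yields at most one trustworthy candidate per frame.

### Saliency

The saliency front end follows the classic center-surround architecture.
Channels: luminance `I = (R+G+B)/3`; opponency `r−g` and `b−(r+g)/2` on
channels normalized by luminance (zeroed where luminance is below 1/10 of
its frame maximum, so near-black pixels cannot blow up the ratios);
orientation energy from zero-mean Gabor kernels (0.25 cycles/px) at 0°,
45°, 90°, 135° applied to luminance pyramid levels. Each channel is
expanded into a 9-level dyadic Gaussian pyramid (5×5 binomial kernel
[1 4 6 4 1]/16, reflect borders, decimation by 2). Center-surround maps
are `|level c − upsample(level s)|` for c ∈ {2,3,4}, s = c + δ, δ ∈ {3,4}
(bilinear upsampling; a nearest-neighbor variant exists for oracle
testing, and the two differ by under 10 % of the map maximum). The
normalization `N(·)` rescales a map to [0,1] and multiplies by `(1−m̄)²`,
`m̄` being the mean of 3×3 local maxima ≥ 0.05 excluding one instance of
the global maximum: maps with one dominant peak keep their weight, maps
with many comparable peaks are suppressed. Normalized maps are summed per
channel family at working scale 4, normalized again, averaged, min-max
rescaled, and bilinearly upsampled to the frame grid. A frame with no
contrast anywhere yields an all-zero map (the min-max rescale guards the
zero-range case). Gabor filtering is applied only to the pyramid levels
the center-surround pairs touch (2–8), which keeps the per-frame cost at
about 0.1 s for 640×480 on one CPU core.

All constants sit in `SaliencyConfig`; they are the published defaults of
the architecture, not fitted values.

### Background model

Appearance is summarized by two 64-bin histograms — hue (circular,
`bin = ⌊h·B⌋ mod B`, counted only where hue is defined) and intensity
(`bin = min(⌊i·B⌋, B−1)`) — over a reference region, normalized to sum 1.
64 bins keep the 0.00015 foreground threshold meaningful (uniform mass
would be 0.0156) while a region of ~10⁵ pixels still populates the
histogram densely. On the first frame the region is a trapezoid anchored
at the bottom edge (full frame width at the bottom, half width at the top,
a quarter of the frame high — the shape is configurable). On every later
frame the model is updated with the histograms of all pixels whose
saliency is below 0.5 of the frame maximum — salient regions are withheld
because they are less likely to be background — via the convex per-bin
blend with α = 0.1, then renormalized (the update-region pixel count
varies per frame). The update is linear, so the model contracts toward the
per-frame histogram with factor β = 0.9 exactly; α = 0.1 makes the model's
memory span a few tens of frames, matching the time scale of a passing
cloud at 5 fps. If a frame's update mask is empty (everything salient),
the model is left unchanged.

Order of operations per frame: **update, then classify**. The frame being
classified has already contributed (with weight α) to the model it is
judged against. This is what makes a global intensity ramp nearly
invisible to the foreground test: any intensity bin holding at least
0.15 % of the current frame clears the 0.00015 threshold from the current
frame's own contribution. The alternative order (classify against the
previous model) was measured to produce several-fold larger false-alarm
transients under intensity ramps and recovers more slowly.

The update region defaults to *all* non-salient pixels. Restricting it to
the lower half of the frame (available as `update_region: lower_half`,
as is `trapezoid`) was found to leave the far field unlearned, so
approaching texture anomalies generate persistent false foreground; with
the full region the false-alarm fraction after a cloud ramp returns to
~0.01 % of the frame. Classification: foreground iff hue-bin mass
< 0.00015 (skipped for achromatic pixels) OR intensity-bin mass < 0.00015.
A region with no chromatic pixels at all falls back to a uniform hue
histogram, which disables the hue test rather than erroring.

### Fusion, detection, tracking

The most salient region is the connected component (8-connectivity)
containing the global saliency maximum, grown to all contiguous pixels
≥ 0.75 of that maximum. It is AND-ed with the foreground mask; components
below 5 px are removed as noise; the largest remaining component becomes
the frame's detection if it covers ≥ 30 px, ties broken toward the blob
lower in the image (nearer the machine). Labeled cooling-box regions can
be zeroed before blob extraction (suppression masks). The tracker gates a
new detection against each live track with a ±20 px box in x and y
(Chebyshev-nearest eligible track wins, ties to the smaller id), confirms
a track at ≥ 2 hits within 3 consecutive frames (confirmation is sticky),
and retires it after 3 consecutive misses. 20 px covers the inter-frame
image motion of ground points farther than ≈ 2.8 m at 0.25 m of travel per
frame; closer than that the track fragments, which is harmless because
confirmation has already happened on approach.

### Geometry and evaluation

Ground distance of image row `r` uses the flat-ground model
`d = h / tan θ(r)` with `θ(r)` varying linearly across the vertical field
of view (top row = tilt − vfov/2, bottom row = tilt + vfov/2). The
linear-in-angle approximation differs from the true tangent-plane
projection by under 8 % over the default field of view — smaller than the
one-significant-figure precision of the range figures it reproduces — and
a `pinhole: true` flag switches to the exact model. Evaluation is
frame-level: a detection centroid inside a nest bbox is a TP, a detection
matching nothing an FP, an unmatched nest label an FN, an empty frame a
TN. With an evaluation-distance limit, labels farther than the limit
(from the label's distance field, else from the bbox bottom row) are
dropped *before* scoring; growing the limit can only move counts
monotonically (TP up, FP down, FN up, TN down). Printed-rate comparisons
truncate to two decimals, matching how the reproduced rates were printed
(0.3853 → 0.38).

## Synthetic scenes

The generator renders what the algorithm assumes rather than what a field
camera photographs. Scenes are authored in HSI over *world* ground
coordinates: a green base (hue 0.33, saturation 0.45, intensity 0.5) with
band-limited Gaussian noise (hue σ = 0.01 of the hue circle, intensity
σ = 0.05, smoothed at ~0.1 m correlation length) and a sinusoidal row
pattern (0.5 m period, amplitude 0.04) parallel to the driving direction;
per frame the camera advances `speed/fps` m (defaults 1.25 m/s, 5 fps)
and each pixel samples the texture at its ground intersection, so
egomotion re-images the same field. Nests are brown ellipses (hue 0.08 —
16 of 64 hue bins away from the background, outside hue-noise reach) of
0.15 m diameter with 3–5 lighter egg speckles, projected through the
camera geometry; labels carry the pixel-exact bbox, the true camera–nest
distance, and a stable nest id. Cloud ramps scale all intensities by a
triangular factor dipping to 1 − depth; shadow polygons scale intensity
only, preserving hue. Rendering is bit-exact reproducible from
(config, seed).

Spurious single-frame objects (red discs, radius 8 px ≈ 200 px area —
large enough to win the per-frame saliency competition, which a few-pixel
speckle reliably loses at the working scale) are injected per frame with
the configured probability. Injection sites avoid nest bboxes, keep
≥ 80 px from injections in the two preceding frames, and can additionally
avoid a caller-supplied position list (e.g. the raw detections of a clean
run, ±3 frames, 40 px): without those separations an injection can land
inside the association gate of an existing track and be *correctly*
confirmed as a repeated detection, which is association contamination
rather than the single-frame-event scenario the injections exist to test.

What the generator does not emulate: real crop structure and occlusion,
camera vibration and rolling shutter, specular soil, lighting direction,
perspective texture gradients beyond the geometric mapping, and sensor
noise; saturation is constant per material. Bright palette + noise
combinations can leave the HSI gamut and clip, slightly distorting hue at
the clipped pixels (as a saturating sensor would). Detection rates
measured on these scenes therefore validate the algorithm's mechanics and
internal consistency — not field performance.

## Problem sizes and numerical choices

End-to-end checks run at the study conditions (640×480, 5 fps, 1.25 m/s,
0.15 m nests): ten 40-frame approach sequences for nest recovery, one
100-frame sequence for false-positive suppression, three 46-frame
sequences for cloud-ramp adaptation (the ramp-to-baseline ratio is pooled
over the three, because single-sequence baselines of ~0.1 % of the frame
are dominated by terrain luck). Degenerate inputs are defined, not
special-cased: empty saliency maps gate nothing and detect nothing,
constant maps have no most-salient region, zero-denominator rates raise
an undefined-metric signal instead of returning 0, and empty histogram
regions raise rather than silently producing zeros. All randomness flows
through `numpy.random.default_rng` seeds carried in configs.

## Known limitations

* The appearance model assumes a homogeneous field; heterogeneous crops
  or bare-soil patches inflate the false-positive rate (visible even in
  the synthetic scenes, where texture tails produce FP blobs before
  tracking).
* One detection per frame: a second simultaneous obstacle is invisible
  until the first leaves the frame or is suppressed.
* The box-gated tracker fragments tracks closer than ≈ 2.8 m and does not
  predict motion; it is deliberately the naive scheme, not a Kalman
  tracker.
* Flat-ground geometry: slopes and ruts bias distances; there is no lens
  model.
* No real-time engineering: ~0.1 s per 640×480 frame single-threaded.
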