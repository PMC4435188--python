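# nestsentry

Detection of ground-lying bird nests from a forward-moving agricultural
camera, by fusing bottom-up visual saliency with an incrementally updated
appearance background model.

## The problem

Ground-nesting farmland birds (skylark, corn bunting, grey partridge) breed
inside row crops, where mechanical weeding destroys a large fraction of
nests. A camera mounted on the weeding machine could trigger an avoidance
action — but nests are small, lie *on* the ground, and are often lower than
the crop, so the usual obstacle-detection route (anything sticking up out
of the ground plane, from stereo or structure-from-motion) cannot see them.
`nestsentry` implements an appearance-driven alternative for a monocular
RGB camera on a moving vehicle:

1. **Visual saliency** (Itti–Koch center-surround architecture): nine-level
   dyadic Gaussian pyramids per channel; feature maps
   `F(c, s) = |F(c) − interp(F(s))|` for intensity, red–green and
   blue–yellow opponency, and four Gabor orientations; a peak-promoting
   normalization `N(·)` that multiplies each map by `(1 − m̄)²`, where `m̄`
   is the mean of its local maxima excluding the global one; conspicuity
   maps summed at a working scale and averaged into a single map in [0, 1].
   Small regions that stand out from a homogeneous field score high.
2. **Incremental background model**: the field's appearance is summarized
   by normalized hue and intensity histograms (64 bins each) of a reference
   region — initially a trapezoid of near ground, afterwards all
   *non-salient* pixels of each frame — updated per bin as

   `uHist_t[k] = α·Hist_t[k] + β·Hist_{t−1}[k]`,  `α + β = 1`,

   and renormalized. A pixel is **foreground** when the model mass of its
   hue bin or its intensity bin falls below 0.00015. The update keeps the
   model tracking global changes (a cloud covering the sun) while the
   saliency gate keeps obstacles out of it.
3. **Fusion**: the connected saliency region containing the global maximum
   is binarized and AND-ed with the foreground mask; blobs under 5 px are
   noise; the largest remaining blob is the frame's single detection if it
   covers ≥ 30 px.
4. **Temporal constraint**: a naive tracker gates detections with a
   ±20 px box in x and y; a track is confirmed as a nest when it is hit in
   two out of three consecutive frames, which removes single-frame
   false positives.
5. **Ground geometry**: with camera height `h` and a ray `θ` below the
   horizontal, ground distance is `d = h / tan θ`; for the default rig
   (h = 0.8 m, tilt 20°, vertical FOV 34°) the footprint spans ≈ 1–15 m.
   Image rows convert to meters for detection-distance statistics and
   distance-limited evaluation, where per-frame
   `TPR = TP/(TP+FN)` and `PPV = TP/(TP+FP)`.

Since no field recordings are distributed with the package, a seeded
synthetic scene generator (`nestsentry.synthetic`) renders the situations
the detector assumes — homogeneous row-crop texture under forward
egomotion, 0.15 m nests with egg speckles, cloud intensity ramps, shadows,
spurious single-frame objects — with pixel-exact labels and true ground
distances, so the whole pipeline is testable end to end.

## Worked example

Drive toward a single 0.15 m nest placed 10 m ahead, at 1.25 m/s and
5 fps (40 frames, 640×480), then score detections within a 4 m evaluation
distance:

```python
from dataclasses import replace
from nestsentry import (SceneConfig, NestSpec, PipelineConfig,
                        render_sequence, run_pipeline,
                        detection_distance_stats)

scene = SceneConfig(seed=3, n_frames=40, nests=(NestSpec(forward_m=10.0),))
seq = render_sequence(scene)
cfg = replace(PipelineConfig(), max_eval_distance_m=4.0)
res = run_pipeline(seq.frames, cfg, seq.labels)
print(res.metrics)
stats = detection_distance_stats(res.tracker.confirmed_log, seq.labels,
                                 cfg.geometry)
print(stats["n_detected"], stats["mean_detection_distance_m"])
```

prints

```
{'tp': 10, 'fp': 25, 'fn': 0, 'tn': 5, 'tpr': 1.0, 'ppv': 0.2857142857142857}
1 4.0
```

Every frame in which the nest is labeled within 4 m is a true positive
(TPR 1.0); texture anomalies in the synthetic field produce raw false
positives (PPV 0.29 before the temporal constraint — the reason the
tracker exists). The confirmed-track stream locks onto the nest at a
ground distance of 4.0 m (`confirmed.csv` rows at x ≈ 317, the nest
column, from frame 24 on).

The same flow is available from the shell:

```
nestsentry simulate --seed 3 --output frames/
nestsentry detect --input frames/ --output detections.csv --track
nestsentry evaluate --input frames/ --labels frames/labels.csv \
    --max-eval-distance 4.0
nestsentry e2e --seed 3 --workdir run3/
```

A fully annotated default configuration ships in `configs/default.yaml`.

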