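# Complete default configuration for the nestsentry detection pipeline.
# Every key is optional; omitted keys take the values shown here.

saliency:
  n_levels: 9              # dyadic Gaussian pyramid depth
  center_scales: [2, 3, 4] # fine (center) pyramid scales
  surround_deltas: [3, 4]  # surround scale = center + delta
  working_scale: 4         # common scale for conspicuity summation
  gabor_frequency: 0.25    # cycles/pixel of the orientation filters
  luminance_gate: 0.1      # color opponency zeroed below this luminance frac
  peak_threshold: 0.05     # local maxima below this ignored by N(.)
  upsample_order: 1        # 1 = bilinear between pyramid scales

background:
  bins: 64                 # histogram bins for hue and for intensity
  alpha: 0.1               # weight of the current frame in the update
                           # (beta = 1 - alpha weights the previous model)
  hue_threshold: 0.00015   # bin mass below which a hue is foreground
  intensity_threshold: 0.00015
  gate_fraction: 0.5       # pixels >= this fraction of the saliency max
                           # are excluded from the model update
  trapezoid_bottom_frac: 1.0   # initial reference region: bottom width
  trapezoid_top_frac: 0.5      # top width (fractions of frame width)
  trapezoid_height_frac: 0.25  # height (fraction of frame height)
  update_region: full      # pixels feeding the update: full | lower_half | trapezoid
  smooth_input: false      # optional Gaussian pre-smoothing before HSI
  smooth_sigma: 1.0

fusion:
  min_blob_area: 5             # blobs below this many pixels are noise
  detection_area_threshold: 30 # largest blob must reach this to be emitted
  binarize_fraction: 0.75      # most-salient region grows to this frac of max
  connectivity: 8              # connected-component connectivity (4 or 8)

tracker:
  max_dx: 20               # association box gate, pixels
  max_dy: 20
  window: 3                # temporal window length (frames)
  required_hits: 2         # hits within the window needed to confirm
  max_misses: 3            # consecutive misses before a track retires

geometry:
  height_m: 0.8            # camera height above flat ground
  tilt_deg: 20.0           # downward tilt of the optical axis
  vfov_deg: 34.0           # vertical field of view
  hfov_deg: 43.0           # horizontal field of view
  image_width: 640
  image_height: 480
  pinhole: false           # true = tangent-plane row model instead of
                           # linear-in-angle

max_eval_distance_m: null  # drop nest labels beyond this distance when scoring
rescale_width: 640         # frames are rescaled to this size on input
rescale_height: 480
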