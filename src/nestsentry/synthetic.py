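"""Seeded synthetic field scenes with exact ground truth.

The generator emulates the statistical structure the detector assumes:
a homogeneous row-crop ground plane seen from a forward-moving camera,
small ground-lying nests with heated-egg speckles, global intensity ramps
(a cloud covering the sun), and optional shadow regions.  Scenes are
authored in hue/saturation/intensity — the channels the background model
histograms — as functions of *world* ground coordinates, so forward
egomotion re-images the same texture from frame to frame.  Every frame
with a visible nest gets a pixel-exact bounding-box label carrying the
true camera-nest ground distance.

Sequences are bit-exact reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .background import hsi_to_rgb
from .evaluation import GroundTruthLabel, ObjectClass
from .frames import ImageFrame
from .geometry import CameraGeometry, distance_to_pixel_row, ground_range, \
    pixel_row_to_distance

__all__ = [
    "BackgroundPalette",
    "NestSpec",
    "CloudRamp",
    "SceneConfig",
    "SyntheticSequence",
    "render_sequence",
    "inject_spurious",
    "write_sequence",
]


@dataclass(frozen=True)
class BackgroundPalette:
    """Appearance of the row-crop ground plane.

    Hue noise is a small fraction of the hue circle and intensity noise a
    few percent of full scale — strong enough to populate histograms,
    weak enough to satisfy the homogeneity assumption.  The sinusoidal
    row pattern runs parallel to the driving direction.
    """

    base_hue: float = 0.33          # green, hue circle in [0, 1)
    base_saturation: float = 0.45
    base_intensity: float = 0.5
    hue_noise_sigma: float = 0.01
    intensity_noise_sigma: float = 0.05
    row_period_m: float = 0.5
    row_amplitude: float = 0.04
    noise_resolution_m: float = 0.05
    noise_smooth_cells: float = 2.0


@dataclass(frozen=True)
class NestSpec:
    """One ground-lying nest: world position, size, appearance."""

    forward_m: float                 # along the driving direction, from frame-0 camera
    lateral_m: float = 0.0           # left(-) / right(+) of the camera axis
    diameter_m: float = 0.15
    hue: float = 0.08                # brown; >= 10 of 64 hue bins from green
    saturation: float = 0.55
    intensity: float = 0.42
    egg_count: int = 4               # lighter speckles, like 3-5 heated eggs


@dataclass(frozen=True)
class CloudRamp:
    """Global intensity dip: bright -> darker -> bright, triangular."""

    start_frame: int
    depth: float = 0.4               # fraction of intensity removed at the dip
    duration: int = 20               # frames from ramp start to full recovery

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth < 1.0:
            raise ValueError("cloud depth must lie in [0, 1)")

    def factor(self, frame: int) -> float:
        if frame < self.start_frame or frame > self.start_frame + self.duration:
            return 1.0
        phase = (frame - self.start_frame) / self.duration
        return 1.0 - self.depth * (1.0 - abs(2.0 * phase - 1.0))


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic recording."""

    seed: int = 0
    n_frames: int = 40
    width: int = 640
    height: int = 480
    speed_mps: float = 1.25          # ~4.5 km/h, typical scouting speed
    fps: float = 5.0
    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    background: BackgroundPalette = field(default_factory=BackgroundPalette)
    nests: tuple[NestSpec, ...] = ()
    cloud: CloudRamp | None = None
    shadow_polygon: tuple[tuple[float, float], ...] | None = None  # image (x, y)
    shadow_factor: float = 0.6
    spurious_rate: float = 0.0

    @property
    def step_m(self) -> float:
        return self.speed_mps / self.fps


@dataclass
class SyntheticSequence:
    frames: list[ImageFrame]
    labels: list[GroundTruthLabel]
    camera_log: pd.DataFrame          # frame, camera_forward_m
    config: SceneConfig
    spurious: list[tuple[int, float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _world_textures(cfg: SceneConfig, rng: np.random.Generator):
    """Band-limited noise fields over the ground footprint of the drive."""
    pal = cfg.background
    _, far = ground_range(cfg.geometry)
    res = pal.noise_resolution_m
    fwd_max = cfg.n_frames * cfg.step_m + far + 1.0
    lat_max = far * math.tan(math.radians(cfg.geometry.hfov_deg / 2.0)) + 1.0
    n_fwd = int(math.ceil(fwd_max / res)) + 2
    n_lat = int(math.ceil(2 * lat_max / res)) + 2

    def smooth_noise() -> np.ndarray:
        white = rng.standard_normal((n_fwd, n_lat))
        sm = ndimage.gaussian_filter(white, sigma=pal.noise_smooth_cells)
        sd = sm.std()
        return sm / sd if sd > 0 else sm

    return smooth_noise(), smooth_noise(), lat_max, res


def _paint_ellipse(center_rc, semi_rc, shape):
    """Boolean ellipse mask on the frame grid; returns (mask, bbox) or None."""
    (cr, cc), (ar, ac) = center_rc, semi_rc
    ar, ac = max(ar, 1e-6), max(ac, 1e-6)
    r0 = max(int(math.floor(cr - ar)), 0)
    r1 = min(int(math.ceil(cr + ar)), shape[0] - 1)
    c0 = max(int(math.floor(cc - ac)), 0)
    c1 = min(int(math.ceil(cc + ac)), shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return None
    rr, cc_grid = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    inside = (((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2) <= 1.0
    if not inside.any():
        return None
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return mask, (c0, r0, c1, r1)


def render_sequence(cfg: SceneConfig) -> SyntheticSequence:
    """Render a full sequence with labels and a camera log.

    Per frame the camera advances ``speed / fps`` meters.  Ground texture
    is sampled from seeded world-coordinate noise fields; nests are
    projected through the camera geometry to image ellipses with egg
    speckles; the cloud ramp scales all intensities; an optional shadow
    polygon darkens intensity while preserving hue.  A nest behind the
    camera or outside the footprint simply emits no label.
    """
    geom = cfg.geometry
    pal = cfg.background
    rng = np.random.default_rng(cfg.seed)
    hue_noise, int_noise, lat_max, res = _world_textures(cfg, rng)
    near, far = ground_range(geom)

    h, w = cfg.height, cfg.width
    geom = replace(geom, image_width=w, image_height=h)
    rows = np.arange(h)
    d_row = pixel_row_to_distance(rows, geom)                      # (H,)
    phi = np.radians(geom.hfov_deg) * (np.arange(w) / (w - 1) - 0.5)  # (W,)
    lateral = d_row[:, None] * np.tan(phi)[None, :]                # (H, W)

    # fixed egg layouts per nest (world-frame, unit nest coordinates)
    egg_layouts = []
    for nest in cfg.nests:
        n_eggs = int(nest.egg_count)
        ang = rng.uniform(0, 2 * np.pi, n_eggs)
        rad = np.sqrt(rng.uniform(0.05, 0.45, n_eggs))
        egg_layouts.append(np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1))

    shadow_mask = None
    if cfg.shadow_polygon is not None:
        ys = [p[1] for p in cfg.shadow_polygon]
        xs = [p[0] for p in cfg.shadow_polygon]
        rr, cc = draw_polygon(ys, xs, shape=(h, w))
        shadow_mask = np.zeros((h, w), dtype=bool)
        shadow_mask[rr, cc] = True

    frames: list[ImageFrame] = []
    labels: list[GroundTruthLabel] = []
    log_rows = []
    for fi in range(cfg.n_frames):
        cam_y = fi * cfg.step_m
        fwd = cam_y + d_row[:, None] + np.zeros_like(lateral)
        coords = np.stack([fwd / res, (lateral + lat_max) / res])
        hn = ndimage.map_coordinates(hue_noise, coords, order=1, mode="nearest")
        inoise = ndimage.map_coordinates(int_noise, coords, order=1, mode="nearest")

        hue = np.mod(pal.base_hue + pal.hue_noise_sigma * hn, 1.0)
        sat = np.full((h, w), pal.base_saturation)
        inten = (pal.base_intensity + pal.intensity_noise_sigma * inoise
                 + pal.row_amplitude * np.sin(2 * np.pi * lateral / pal.row_period_m))

        for nest_id, (nest, eggs) in enumerate(zip(cfg.nests, egg_layouts)):
            d_rel = nest.forward_m - cam_y
            if d_rel < max(near, 0.05) or d_rel - nest.diameter_m / 2 > far:
                continue
            r_near = distance_to_pixel_row(max(d_rel - nest.diameter_m / 2, near),
                                           geom, clip=True)
            r_far = distance_to_pixel_row(min(d_rel + nest.diameter_m / 2, far),
                                          geom, clip=True)
            cr = (r_near + r_far) / 2.0
            ar = max((r_near - r_far) / 2.0, 0.0)
            phi_c = math.atan2(nest.lateral_m, d_rel)
            cc_ = (math.degrees(phi_c) / geom.hfov_deg + 0.5) * (w - 1)
            ac = (math.degrees(math.atan(nest.diameter_m / 2 / d_rel))
                  / geom.hfov_deg) * (w - 1)
            painted = _paint_ellipse((cr, cc_), (ar, ac), (h, w))
            if painted is None:
                continue
            mask, bbox = painted
            hue[mask] = nest.hue
            sat[mask] = nest.saturation
            inten[mask] = nest.intensity
            # egg speckles: lighter, slightly yellower dots inside the nest
            if ar >= 1.0 and ac >= 2.0:
                for u, v in eggs:
                    egg = _paint_ellipse((cr + v * ar * 0.8, cc_ + u * ac * 0.8),
                                         (max(ar * 0.18, 0.6), max(ac * 0.18, 0.6)),
                                         (h, w))
                    if egg is not None:
                        emask = egg[0] & mask
                        hue[emask] = 0.13
                        inten[emask] = min(nest.intensity + 0.2, 1.0)
            x0, y0, x1, y1 = bbox
            labels.append(GroundTruthLabel(
                frame_index=fi, object_class=ObjectClass.NEST,
                bbox=(float(x0), float(y0), float(max(x1, x0 + 1)),
                      float(max(y1, y0 + 1))),
                ground_distance_m=float(d_rel),
                object_id=nest_id,
            ))

        if shadow_mask is not None:
            inten = np.where(shadow_mask, inten * cfg.shadow_factor, inten)
        if cfg.cloud is not None:
            inten = inten * cfg.cloud.factor(fi)

        rgb = hsi_to_rgb(hue, sat, np.clip(inten, 0.0, 1.0))
        frames.append(ImageFrame(rgb, fi))
        log_rows.append({"frame": fi, "camera_forward_m": cam_y})

    seq = SyntheticSequence(frames, labels, pd.DataFrame(log_rows), cfg)
    if cfg.spurious_rate > 0:
        seq = inject_spurious(seq, cfg.spurious_rate, cfg.seed + 1)
    return seq


# ---------------------------------------------------------------------------
# spurious single-frame objects (to provoke raw false positives)
# ---------------------------------------------------------------------------

def inject_spurious(seq: SyntheticSequence, rate: float, seed: int,
                    avoid: list[tuple[int, float, float]] | None = None,
                    avoid_sep: float = 40.0) -> SyntheticSequence:
    """Add single-frame high-contrast speckle objects at random positions.

    Each frame independently receives one spurious object with probability
    ``rate``.  Positions avoid nest bboxes and keep a minimum separation
    from injections in the two preceding frames, so every injected object
    is a genuine single-frame event that the 2-of-3 temporal constraint
    must remove rather than a chance repeated detection.  ``avoid``
    optionally lists further (frame, x, y) positions — e.g. the raw
    detections of a clean run of the detector — that injections must stay
    ``avoid_sep`` pixels away from in nearby frames, so spurious objects
    cannot collide with pre-existing tracks by chance.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0:
        return seq
    rng = np.random.default_rng(seed)
    h, w = seq.frames[0].height, seq.frames[0].width
    margin, radius, min_sep = 40, 8, 80
    nest_boxes: dict[int, list[tuple[float, float, float, float]]] = {}
    for lab in seq.labels:
        nest_boxes.setdefault(lab.frame_index, []).append(lab.bbox)

    frames = [ImageFrame(f.pixels.copy(), f.frame_index) for f in seq.frames]
    injected: list[tuple[int, float, float]] = []
    for fi, frame in enumerate(frames):
        hit = rng.random() < rate
        recent_inj = [(x, y) for (f, x, y) in injected if f >= fi - 2]
        avoid_near = ([(x, y) for (f, x, y) in avoid if abs(f - fi) <= 3]
                      if avoid else [])
        if not hit:
            continue
        pos = None
        for _ in range(200):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            near_nest = any(b[0] - margin <= x <= b[2] + margin
                            and b[1] - margin <= y <= b[3] + margin
                            for b in nest_boxes.get(fi, []))
            near_prev = any(max(abs(x - px), abs(y - py)) < min_sep
                            for px, py in recent_inj)
            near_avoid = any(max(abs(x - px), abs(y - py)) < avoid_sep
                             for px, py in avoid_near)
            if not (near_nest or near_prev or near_avoid):
                pos = (x, y)
                break
        if pos is None:
            continue
        x, y = pos
        rr, cc = np.mgrid[0:h, 0:w]
        disc = (rr - y) ** 2 + (cc - x) ** 2 <= radius ** 2
        px = frame.pixels
        px[disc] = (0.85, 0.1, 0.1)  # saturated red speckle, novel hue
        frame.pixels = px
        injected.append((fi, x, y))
    return SyntheticSequence(frames, seq.labels, seq.camera_log, seq.config,
                             spurious=injected)


def write_sequence(seq: SyntheticSequence, outdir) -> None:
    """Persist a sequence as PNG frames + labels.csv + camera_log.csv."""
    import imageio.v3 as iio
    from pathlib import Path

    from .evaluation import write_labels

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for f in seq.frames:
        iio.imwrite(out / f"frame_{f.frame_index:05d}.png",
                    (f.pixels * 255).round().astype(np.uint8))
    write_labels(seq.labels, out / "labels.csv")
    seq.camera_log.to_csv(out / "camera_log.csv", index=False)
    if seq.spurious:
        pd.DataFrame(seq.spurious, columns=["frame", "x", "y"]).to_csv(
            out / "spurious.csv", index=False)
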