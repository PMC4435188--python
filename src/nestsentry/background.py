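"""Appearance background model with a saliency-gated incremental update.

A homogeneous row-crop field can be summarized by the normalized hue and
intensity histograms of a reference region of ground.  On the first frame
that region is a fixed trapezoid near the camera; on every later frame
the histograms of the *non-salient* part of the update region are blended
into the model with the convex update

    uHist_t[k] = alpha * Hist_t[k] + beta * Hist_{t-1}[k],   alpha + beta = 1,

followed by renormalization (the pixel count of the update region varies
from frame to frame).  A pixel is then classified as foreground when the
model probability mass of its hue bin or of its intensity bin falls below
a small threshold: novel appearance = obstacle candidate.  Gating the
update on low saliency keeps obstacles themselves from being absorbed
into the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .frames import ImageFrame
from .saliency import SaliencyMap

__all__ = [
    "HSIImage",
    "ReferenceRegion",
    "AppearanceHistogram",
    "UpdateParams",
    "BackgroundThresholds",
    "BackgroundConfig",
    "BackgroundModel",
    "EmptyRegionError",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "initial_reference_region",
    "compute_histograms",
    "saliency_gated_mask",
    "update_model",
    "classify_foreground",
]


class EmptyRegionError(ValueError):
    """Histogram requested over an empty pixel set."""


@dataclass
class HSIImage:
    """Hue-saturation-intensity decomposition of an RGB frame.

    Hue lies in [0, 1) and is circular; ``hue_defined`` is False for
    achromatic pixels (saturation 0), where hue is meaningless.
    """

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    hue_defined: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class ReferenceRegion:
    """Polygonal image region whose histograms seed the background model."""

    polygon: list[tuple[float, float]]  # (x, y) vertices, image coordinates
    mask: np.ndarray  # H x W boolean

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("reference region is empty")


@dataclass
class AppearanceHistogram:
    """Normalized hue + intensity histograms of a region."""

    hue_bins: np.ndarray
    intensity_bins: np.ndarray
    bin_count: int
    normalized: bool = True

    def __post_init__(self) -> None:
        self.hue_bins = np.asarray(self.hue_bins, dtype=float)
        self.intensity_bins = np.asarray(self.intensity_bins, dtype=float)
        if len(self.hue_bins) != self.bin_count or len(self.intensity_bins) != self.bin_count:
            raise ValueError("histogram length does not match bin_count")
        if (self.hue_bins < 0).any() or (self.intensity_bins < 0).any():
            raise ValueError("histogram bins must be non-negative")
        if self.normalized:
            for h in (self.hue_bins, self.intensity_bins):
                if abs(h.sum() - 1.0) > 1e-9:
                    raise ValueError("normalized histogram must sum to 1")


@dataclass(frozen=True)
class UpdateParams:
    """Convex blending weights of the incremental update; alpha + beta = 1."""

    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class BackgroundThresholds:
    """Probability-mass thresholds below which a bin means 'foreground'."""

    hue_threshold: float = 0.00015
    intensity_threshold: float = 0.00015

    def __post_init__(self) -> None:
        for v in (self.hue_threshold, self.intensity_threshold):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class BackgroundConfig:
    """All tunables of the background model in one place."""

    bins: int = 64
    alpha: float = 0.1
    hue_threshold: float = 0.00015
    intensity_threshold: float = 0.00015
    gate_fraction: float = 0.5
    #: initial trapezoid: widths as fractions of frame width, height as a
    #: fraction of frame height measured up from the bottom edge
    trapezoid_bottom_frac: float = 1.0
    trapezoid_top_frac: float = 0.5
    trapezoid_height_frac: float = 0.25
    #: which pixels feed the incremental update (always intersected with
    #: the non-salient gate): "full" (all non-salient pixels),
    #: "lower_half", or "trapezoid"
    update_region: str = "full"
    #: optional Gaussian pre-smoothing of the RGB frame before conversion
    smooth_input: bool = False
    smooth_sigma: float = 1.0


# ---------------------------------------------------------------------------
# color space
# ---------------------------------------------------------------------------

def rgb_to_hsi(frame: ImageFrame | np.ndarray) -> HSIImage:
    """Standard HSI conversion via the arccos hue formulation.

    Intensity is the channel mean; saturation is 1 - min/intensity (zero
    for black pixels); hue is the angle

        theta = arccos( ((R-G) + (R-B)) / 2 / sqrt((R-G)^2 + (R-B)(G-B)) )

    taken as theta for B <= G and 2*pi - theta otherwise, mapped to
    [0, 1).  Achromatic pixels get ``hue_defined`` False.
    """
    px = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    intensity = px.mean(axis=2)
    mn = px.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(intensity > 1e-12, 1.0 - mn / np.maximum(intensity, 1e-12), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    defined = (saturation > 1e-12) & (den > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arccos(np.clip(num / np.maximum(den, 1e-12), -1.0, 1.0))
    hue = np.where(b <= g, theta, 2.0 * np.pi - theta) / (2.0 * np.pi)
    hue = np.where(defined, np.mod(hue, 1.0), 0.0)
    return HSIImage(hue, saturation, intensity, defined)


def hsi_to_rgb(hue: np.ndarray, saturation: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Inverse HSI conversion (sector formulas); returns H x W x 3 in [0, 1].

    Used by the synthetic-scene renderer so that scenes can be authored
    directly in hue/intensity, the channels the background model sees.
    Out-of-gamut combinations (leading channel i*(1 + 2s) above 1) are
    clipped.
    """
    h = np.mod(np.asarray(hue, dtype=float), 1.0) * 2.0 * np.pi
    s = np.clip(np.asarray(saturation, dtype=float), 0.0, 1.0)
    i = np.clip(np.asarray(intensity, dtype=float), 0.0, 1.0)

    out = np.zeros(h.shape + (3,), dtype=float)
    third = 2.0 * np.pi / 3.0

    def sector(hh):
        # hh in [0, 2*pi/3): returns the (rising, falling, low) triple
        with np.errstate(divide="ignore", invalid="ignore"):
            x = i * (1.0 + s * np.cos(hh) / np.maximum(np.cos(np.pi / 3.0 - hh), 1e-12))
        z = i * (1.0 - s)
        y = 3.0 * i - (x + z)
        return x, y, z

    m0 = h < third
    m1 = (h >= third) & (h < 2 * third)
    m2 = h >= 2 * third
    x, y, z = sector(h)
    # RGB sector: hue in [0, 120°): B low, R leading
    out[..., 0][m0], out[..., 1][m0], out[..., 2][m0] = x[m0], y[m0], z[m0]
    x, y, z = sector(h - third)
    # GBR sector
    out[..., 1][m1], out[..., 2][m1], out[..., 0][m1] = x[m1], y[m1], z[m1]
    x, y, z = sector(h - 2 * third)
    # BRG sector
    out[..., 2][m2], out[..., 0][m2], out[..., 1][m2] = x[m2], y[m2], z[m2]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# reference region and histograms
# ---------------------------------------------------------------------------

def initial_reference_region(width: int, height: int,
                             cfg: BackgroundConfig | None = None) -> ReferenceRegion:
    """Trapezoidal patch of near-field ground seeding the model.

    Symmetric about the vertical centerline and anchored at the bottom
    edge of the frame; widths and height come from the config.
    """
    cfg = cfg or BackgroundConfig()
    bw = cfg.trapezoid_bottom_frac * (width - 1)
    tw = cfg.trapezoid_top_frac * (width - 1)
    th = cfg.trapezoid_height_frac * (height - 1)
    if bw + tw <= 0 or th <= 0:
        raise ValueError("degenerate trapezoid: zero area")
    cx = (width - 1) / 2.0
    y_bottom = float(height - 1)
    y_top = y_bottom - th
    verts = [
        (cx - bw / 2.0, y_bottom),
        (cx + bw / 2.0, y_bottom),
        (cx + tw / 2.0, y_top),
        (cx - tw / 2.0, y_top),
    ]
    rr, cc = draw_polygon([v[1] for v in verts], [v[0] for v in verts],
                          shape=(height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True
    return ReferenceRegion(verts, mask)


def _hue_bin_index(hue: np.ndarray, bins: int) -> np.ndarray:
    """Circular binning: floor(h * B) mod B."""
    return np.floor(np.mod(hue, 1.0) * bins).astype(np.int64) % bins


def _intensity_bin_index(intensity: np.ndarray, bins: int) -> np.ndarray:
    return np.clip(np.floor(intensity * bins).astype(np.int64), 0, bins - 1)


def compute_histograms(hsi: HSIImage, mask: np.ndarray, bins: int = 64) -> AppearanceHistogram:
    """Normalized hue + intensity histograms of the masked pixels.

    The hue histogram counts only pixels with defined hue; if the region
    contains no chromatic pixels at all, the hue histogram falls back to
    uniform (no hue information => no pixel can fail the hue test).
    Raises :class:`EmptyRegionError` for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("histogram region is empty")
    int_idx = _intensity_bin_index(hsi.intensity[mask], bins)
    int_hist = np.bincount(int_idx, minlength=bins).astype(float)
    int_hist /= int_hist.sum()

    hmask = mask & hsi.hue_defined
    if hmask.any():
        hue_idx = _hue_bin_index(hsi.hue[hmask], bins)
        hue_hist = np.bincount(hue_idx, minlength=bins).astype(float)
        hue_hist /= hue_hist.sum()
    else:
        hue_hist = np.full(bins, 1.0 / bins)
    return AppearanceHistogram(hue_hist, int_hist, bins)


def saliency_gated_mask(salmap: SaliencyMap, gate_fraction: float = 0.5) -> np.ndarray:
    """Pixels eligible for the background update: saliency below the gate.

    True where the saliency value is below ``gate_fraction`` of the frame
    maximum; salient regions are excluded because they are less likely to
    be background.  An all-zero map gates nothing out.
    """
    v = salmap.values
    top = v.max()
    if top <= 0:
        return np.ones_like(v, dtype=bool)
    return v < gate_fraction * top


def update_model(prev: AppearanceHistogram, current: AppearanceHistogram,
                 params: UpdateParams) -> AppearanceHistogram:
    """Incremental model update: per-bin convex blend, then renormalize."""
    if prev.bin_count != current.bin_count:
        raise ValueError(
            f"bin count mismatch: {prev.bin_count} vs {current.bin_count}"
        )
    if not (prev.normalized and current.normalized):
        raise ValueError("update requires normalized histograms")
    a, b = params.alpha, params.beta
    hue = a * current.hue_bins + b * prev.hue_bins
    inten = a * current.intensity_bins + b * prev.intensity_bins
    return AppearanceHistogram(hue / hue.sum(), inten / inten.sum(), prev.bin_count)


def classify_foreground(hsi: HSIImage, model: AppearanceHistogram,
                        thr: BackgroundThresholds | None = None) -> np.ndarray:
    """Per-pixel foreground test against the background model.

    A pixel is foreground when the model mass of its hue bin is below the
    hue threshold, or the mass of its intensity bin is below the intensity
    threshold.  The hue test is skipped for achromatic pixels.
    """
    thr = thr or BackgroundThresholds()
    if not model.normalized:
        raise ValueError("background model must be normalized")
    hue_mass = model.hue_bins[_hue_bin_index(hsi.hue, model.bin_count)]
    int_mass = model.intensity_bins[_intensity_bin_index(hsi.intensity, model.bin_count)]
    fg_hue = hsi.hue_defined & (hue_mass < thr.hue_threshold)
    fg_int = int_mass < thr.intensity_threshold
    return fg_hue | fg_int


# ---------------------------------------------------------------------------
# stateful model driving the per-frame loop
# ---------------------------------------------------------------------------

class BackgroundModel:
    """Holds the running histograms and applies the per-frame recipe.

    Frame 0: build the model from the initial trapezoid (before any
    classification).  Every frame: classify against the current model,
    then blend in the histograms of the non-salient part of the update
    region.  Frames whose update mask is empty leave the model unchanged.
    """

    def __init__(self, cfg: BackgroundConfig | None = None):
        self.cfg = cfg or BackgroundConfig()
        self.params = UpdateParams(self.cfg.alpha)
        self.thresholds = BackgroundThresholds(self.cfg.hue_threshold,
                                               self.cfg.intensity_threshold)
        self.histogram: AppearanceHistogram | None = None
        self._update_mask_base: np.ndarray | None = None

    def prepare(self, frame: ImageFrame) -> HSIImage:
        """Optionally pre-smooth the frame, then convert to HSI."""
        px = frame.pixels
        if self.cfg.smooth_input:
            px = ndimage.gaussian_filter(px, sigma=(self.cfg.smooth_sigma,
                                                    self.cfg.smooth_sigma, 0))
        return rgb_to_hsi(px)

    def _base_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self._update_mask_base is None or self._update_mask_base.shape != shape:
            h, w = shape
            if self.cfg.update_region == "lower_half":
                m = np.zeros(shape, dtype=bool)
                m[h // 2:, :] = True
            elif self.cfg.update_region == "trapezoid":
                m = initial_reference_region(w, h, self.cfg).mask
            elif self.cfg.update_region == "full":
                m = np.ones(shape, dtype=bool)
            else:
                raise ValueError(f"unknown update_region {self.cfg.update_region!r}")
            self._update_mask_base = m
        return self._update_mask_base

    def initialize(self, hsi: HSIImage) -> None:
        region = initial_reference_region(hsi.shape[1], hsi.shape[0], self.cfg)
        self.histogram = compute_histograms(hsi, region.mask, self.cfg.bins)

    def classify(self, hsi: HSIImage) -> np.ndarray:
        if self.histogram is None:
            raise RuntimeError("background model not initialized")
        return classify_foreground(hsi, self.histogram, self.thresholds)

    def update(self, hsi: HSIImage, salmap: SaliencyMap) -> None:
        if self.histogram is None:
            raise RuntimeError("background model not initialized")
        mask = self._base_mask(hsi.shape) & saliency_gated_mask(salmap,
                                                               self.cfg.gate_fraction)
        if not mask.any():
            return  # all-salient frame: keep the previous model
        current = compute_histograms(hsi, mask, self.cfg.bins)
        self.histogram = update_model(self.histogram, current, self.params)

    def state_dict(self) -> dict:
        """JSON-serializable model state for resume/debug."""
        if self.histogram is None:
            return {"initialized": False}
        return {
            "initialized": True,
            "bins": self.histogram.bin_count,
            "alpha": self.params.alpha,
            "hue_bins": self.histogram.hue_bins.tolist(),
            "intensity_bins": self.histogram.intensity_bins.tolist(),
        }
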