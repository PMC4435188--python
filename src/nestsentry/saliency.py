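"""Bottom-up visual saliency (Itti-Koch center-surround architecture).

A saliency map scores each pixel by how strongly its neighborhood stands
out from the surroundings in intensity, color opponency, and orientation.
The computation follows the classic architecture: nine-level dyadic
Gaussian pyramids per channel, center-surround feature maps as absolute
differences between a fine (center) and an upsampled coarse (surround)
scale, a peak-promoting map normalization N(.), per-channel conspicuity
maps summed at a common working scale, and a final average rescaled to
[0, 1] and upsampled back to the frame grid.

Constants (pyramid kernel, center/surround scale pairs, working scale,
N(.) variant) are the published defaults of that architecture and are
exposed in :class:`SaliencyConfig` so alternates can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .frames import ImageFrame

__all__ = [
    "SaliencyConfig",
    "GaussianPyramid",
    "FeatureMap",
    "SaliencyMap",
    "build_pyramid",
    "center_surround",
    "compute_feature_maps",
    "compute_saliency",
    "itti_normalize",
]

#: 5-tap binomial kernel used for pyramid smoothing, [1, 4, 6, 4, 1] / 16.
BINOMIAL_5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: Orientation channels in degrees (orientation of the *structure* the
#: channel responds to: 0° = horizontal bars).
ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class SaliencyConfig:
    """Tunable constants of the saliency computation."""

    n_levels: int = 9
    center_scales: tuple[int, ...] = (2, 3, 4)
    surround_deltas: tuple[int, ...] = (3, 4)
    working_scale: int = 4
    gabor_frequency: float = 0.25  # cycles / pixel at each pyramid level
    #: luminance fraction below which color opponency is zeroed
    luminance_gate: float = 0.1
    #: local maxima below this value (after [0,1] rescale) are ignored by N(.)
    peak_threshold: float = 0.05
    upsample_order: int = 1  # bilinear between scales


@dataclass
class GaussianPyramid:
    """Dyadic Gaussian pyramid: level s is smoothed and decimated 2**s-fold."""

    levels: list[np.ndarray]

    @property
    def depth(self) -> int:
        return len(self.levels)

    def __getitem__(self, s: int) -> np.ndarray:
        return self.levels[s]


@dataclass
class FeatureMap:
    """Center-surround contrast map at the center scale's grid."""

    values: np.ndarray
    channel: str
    center_scale: int
    surround_scale: int


@dataclass
class SaliencyMap:
    """Single-channel map in [0, 1] registered to the source frame grid."""

    values: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("saliency map must be a non-empty 2-D array")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("saliency values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


# ---------------------------------------------------------------------------
# pyramids and center-surround features
# ---------------------------------------------------------------------------

def _smooth(img: np.ndarray) -> np.ndarray:
    """Separable 5x5 binomial smoothing with reflect borders."""
    out = ndimage.correlate1d(img, BINOMIAL_5, axis=0, mode="reflect")
    return ndimage.correlate1d(out, BINOMIAL_5, axis=1, mode="reflect")


def build_pyramid(channel_map: np.ndarray, cfg: SaliencyConfig | None = None) -> GaussianPyramid:
    """Build the dyadic Gaussian pyramid of a single-channel map.

    Level 0 is the input itself; each subsequent level is the previous one
    smoothed with the 5x5 binomial kernel (reflect borders) and decimated
    by keeping every second row and column, so level s has side
    ``ceil(side / 2**s)``.  The pyramid has 9 levels by default; for tiny
    inputs the 1 x 1 floor simply repeats, and the actual depth is
    recorded in :attr:`GaussianPyramid.depth`.
    """
    cfg = cfg or SaliencyConfig()
    img = np.asarray(channel_map, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("pyramid input must be a non-empty 2-D array")
    levels = [img]
    for _ in range(cfg.n_levels - 1):
        prev = levels[-1]
        nxt = _smooth(prev)[::2, ::2]
        if nxt.shape[0] < 1 or nxt.shape[1] < 1:
            break
        levels.append(nxt)
    return GaussianPyramid(levels)


def _resize(img: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    if img.shape == tuple(shape):
        return img
    return resize(img, shape, order=order, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def center_surround(pyr: GaussianPyramid, c: int, s: int, *, channel: str = "",
                    cfg: SaliencyConfig | None = None) -> FeatureMap:
    """Across-scale contrast: |center - surround| on the center grid.

    The coarse surround level is upsampled (bilinear by default) to the
    center level's grid and the pointwise absolute difference taken, so
    the result is non-negative.
    """
    cfg = cfg or SaliencyConfig()
    if s <= c:
        raise ValueError(f"surround scale must exceed center scale, got c={c}, s={s}")
    if s >= pyr.depth:
        raise ValueError(f"surround scale {s} beyond pyramid depth {pyr.depth}")
    center = pyr[c]
    surround = _resize(pyr[s], center.shape, cfg.upsample_order)
    return FeatureMap(np.abs(center - surround), channel, c, s)


# ---------------------------------------------------------------------------
# channel decomposition
# ---------------------------------------------------------------------------

def _decompose_channels(frame: ImageFrame, cfg: SaliencyConfig):
    """Luminance and color-opponency channels of an RGB frame.

    Luminance is the channel mean (R+G+B)/3.  Opponency channels r-g and
    b-(r+g)/2 are computed on channels normalized by luminance, and zeroed
    where luminance is below ``luminance_gate`` of its frame maximum so
    that hue contrast stays meaningful without division blow-ups in dark
    regions.
    """
    px = frame.pixels
    lum = px.mean(axis=2)
    lmax = lum.max()
    valid = lum > cfg.luminance_gate * lmax if lmax > 0 else np.zeros_like(lum, bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(valid[..., None], px / np.maximum(lum, 1e-12)[..., None], 0.0)
    r, g, b = norm[..., 0], norm[..., 1], norm[..., 2]
    rg = r - g
    by = b - (r + g) / 2.0
    return lum, rg, by


def _gabor_kernel(theta_deg: float, frequency: float) -> np.ndarray:
    """Real, zero-mean Gabor kernel tuned to bars oriented at theta_deg.

    The carrier runs perpendicular to the bar orientation so a kernel with
    ``theta_deg=0`` responds most to horizontal structure.
    """
    sigma = 1.0 / (2.0 * frequency)  # about half a period
    half = int(math.ceil(3 * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    t = math.radians(theta_deg)
    # coordinate along the carrier (perpendicular to the bar)
    u = -x * math.sin(t) + y * math.cos(t)
    v = x * math.cos(t) + y * math.sin(t)
    env = np.exp(-(u ** 2 + v ** 2) / (2 * sigma ** 2))
    k = env * np.cos(2 * math.pi * frequency * u)
    k -= env * (k.sum() / env.sum())  # zero total mass, band-pass
    return k


def compute_feature_maps(frame: ImageFrame, cfg: SaliencyConfig | None = None) -> list[FeatureMap]:
    """All center-surround feature maps of a frame.

    Intensity maps come from the luminance pyramid, color maps from the
    red-green and blue-yellow opponency pyramids, and orientation maps
    from Gabor-filtered luminance pyramid levels at 0°, 45°, 90°, 135°.
    Center scales, surround offsets, and filter constants come from
    ``cfg``.
    """
    cfg = cfg or SaliencyConfig()
    lum, rg, by = _decompose_channels(frame, cfg)
    pyr_i = build_pyramid(lum, cfg)
    pyr_rg = build_pyramid(rg, cfg)
    pyr_by = build_pyramid(by, cfg)

    pairs = [(c, c + d) for c in cfg.center_scales for d in cfg.surround_deltas]
    needed = sorted({lv for p in pairs for lv in p})

    maps: list[FeatureMap] = []
    for c, s in pairs:
        maps.append(center_surround(pyr_i, c, s, channel="intensity", cfg=cfg))
        maps.append(center_surround(pyr_rg, c, s, channel="red-green", cfg=cfg))
        maps.append(center_surround(pyr_by, c, s, channel="blue-yellow", cfg=cfg))

    # oriented band-pass pyramids: Gabor-filter only the levels that the
    # center-surround pairs actually touch
    for theta in ORIENTATIONS_DEG:
        kern = _gabor_kernel(theta, cfg.gabor_frequency)
        levels: list[np.ndarray] = []
        for lv in range(pyr_i.depth):
            if lv in needed:
                levels.append(np.abs(ndimage.convolve(pyr_i[lv], kern, mode="reflect")))
            else:
                levels.append(pyr_i[lv])  # placeholder, never used
        opyr = GaussianPyramid(levels)
        for c, s in pairs:
            maps.append(center_surround(opyr, c, s,
                                        channel=f"orientation-{theta:g}", cfg=cfg))
    return maps


# ---------------------------------------------------------------------------
# map normalization and conspicuity
# ---------------------------------------------------------------------------

def itti_normalize(m: np.ndarray, cfg: SaliencyConfig | None = None) -> np.ndarray:
    """Peak-promoting normalization N(.).

    Rescales the map to [0, 1] and multiplies by (1 - m_bar)**2 where
    m_bar is the mean of the local maxima excluding the global maximum.
    Maps with a single dominant peak keep their weight; maps with many
    comparable peaks are suppressed.  Constant maps normalize to zero.
    """
    cfg = cfg or SaliencyConfig()
    m = np.asarray(m, dtype=float)
    rng = m.max() - m.min()
    if rng <= 1e-12:
        return np.zeros_like(m)
    m01 = (m - m.min()) / rng
    localmax = (ndimage.maximum_filter(m01, size=3, mode="reflect") == m01)
    peaks = np.sort(m01[localmax & (m01 >= cfg.peak_threshold)])[::-1]
    others = peaks[1:]  # drop one instance of the global maximum
    m_bar = float(others.mean()) if others.size else 0.0
    return m01 * (1.0 - m_bar) ** 2


def compute_saliency(frame: ImageFrame, cfg: SaliencyConfig | None = None) -> SaliencyMap:
    """Saliency map of a frame on its own pixel grid, values in [0, 1].

    Feature maps are normalized with N(.), summed per channel family
    (intensity / color / orientation) into conspicuity maps at the working
    scale, the conspicuity maps normalized again and averaged, and the
    result min-max rescaled and upsampled to the frame size.  A frame with
    no contrast anywhere yields an all-zero map.
    """
    cfg = cfg or SaliencyConfig()
    fmaps = compute_feature_maps(frame, cfg)
    h, w = frame.height, frame.width
    for _ in range(cfg.working_scale):
        h, w = (h + 1) // 2, (w + 1) // 2
    lum_pyr_shape = (h, w)

    consp = {
        "intensity": np.zeros(lum_pyr_shape),
        "color": np.zeros(lum_pyr_shape),
    }
    orient: dict[str, np.ndarray] = {}
    for fm in fmaps:
        small = _resize(fm.values, lum_pyr_shape, cfg.upsample_order)
        normed = itti_normalize(small, cfg)
        if fm.channel == "intensity":
            consp["intensity"] += normed
        elif fm.channel in ("red-green", "blue-yellow"):
            consp["color"] += normed
        else:
            orient.setdefault(fm.channel, np.zeros(lum_pyr_shape))
            orient[fm.channel] += normed
    o_consp = np.zeros(lum_pyr_shape)
    for omap in orient.values():
        o_consp += itti_normalize(omap, cfg)

    combined = (
        itti_normalize(consp["intensity"], cfg)
        + itti_normalize(consp["color"], cfg)
        + itti_normalize(o_consp, cfg)
    ) / 3.0
    rng = combined.max() - combined.min()
    if rng <= 1e-12:
        return SaliencyMap(np.zeros((frame.height, frame.width)), frame.frame_index)
    combined = (combined - combined.min()) / rng
    full = _resize(combined, (frame.height, frame.width), cfg.upsample_order)
    return SaliencyMap(np.clip(full, 0.0, 1.0), frame.frame_index)
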