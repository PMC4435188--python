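"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the library's code paths: direct 2-D window sums
instead of separable 1-D correlation, explicit index maps instead of
skimage resampling, and per-pixel scalar loops instead of vectorized
conversions.
"""

from __future__ import annotations

import math

import numpy as np

KERNEL_1D = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
KERNEL_2D = np.outer(KERNEL_1D, KERNEL_1D)


def oracle_smooth(img: np.ndarray) -> np.ndarray:
    """5x5 binomial smoothing by direct windowed sums with symmetric borders."""
    padded = np.pad(img, 2, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(5):
        for j in range(5):
            out += KERNEL_2D[i, j] * padded[i:i + img.shape[0], j:j + img.shape[1]]
    return out


def oracle_pyramid(img: np.ndarray, levels: int = 9) -> list[np.ndarray]:
    out = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        out.append(oracle_smooth(out[-1])[::2, ::2])
    return out


def oracle_nearest_upsample(src: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resampling via explicit half-pixel-center index maps."""
    H, W = shape
    h, w = src.shape
    ri = np.minimum(np.floor((np.arange(H) + 0.5) * h / H).astype(int), h - 1)
    ci = np.minimum(np.floor((np.arange(W) + 0.5) * w / W).astype(int), w - 1)
    return src[np.ix_(ri, ci)]


def oracle_center_surround(img: np.ndarray, c: int, s: int) -> np.ndarray:
    pyr = oracle_pyramid(img, levels=s + 1)
    up = oracle_nearest_upsample(pyr[s], pyr[c].shape)
    return np.abs(pyr[c] - up)


def oracle_rgb_to_hsi_pixel(r: float, g: float, b: float):
    """Scalar arccos-formula HSI conversion; hue None when undefined."""
    intensity = (r + g + b) / 3.0
    mn = min(r, g, b)
    saturation = 0.0 if intensity <= 1e-12 else 1.0 - mn / intensity
    num = 0.5 * ((r - g) + (r - b))
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    if saturation <= 1e-12 or den <= 1e-12:
        return None, saturation, intensity
    theta = math.acos(max(-1.0, min(1.0, num / den)))
    hue = theta if b <= g else 2.0 * math.pi - theta
    return (hue / (2.0 * math.pi)) % 1.0, saturation, intensity


def oracle_histograms(hue, sat_defined, intensity, mask, bins):
    """Per-pixel counting of hue/intensity histograms over a mask."""
    hue_counts = np.zeros(bins)
    int_counts = np.zeros(bins)
    H, W = np.asarray(intensity).shape
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            k = min(int(intensity[i, j] * bins), bins - 1)
            int_counts[k] += 1
            if sat_defined[i, j]:
                hue_counts[int(np.floor((hue[i, j] % 1.0) * bins)) % bins] += 1
    if hue_counts.sum() > 0:
        hue_counts = hue_counts / hue_counts.sum()
    else:
        hue_counts = np.full(bins, 1.0 / bins)
    return hue_counts, int_counts / int_counts.sum()


def oracle_gabor_response(img: np.ndarray, theta_deg: float,
                          frequency: float = 0.25) -> np.ndarray:
    """Direct Gabor filtering at one scale (no pyramid), symmetric borders."""
    sigma = 1.0 / (2.0 * frequency)
    half = int(math.ceil(3 * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    t = math.radians(theta_deg)
    u = -x * math.sin(t) + y * math.cos(t)
    v = x * math.cos(t) + y * math.sin(t)
    env = np.exp(-(u ** 2 + v ** 2) / (2 * sigma ** 2))
    k = env * np.cos(2 * math.pi * frequency * u)
    k -= env * (k.sum() / env.sum())
    padded = np.pad(img, half, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    n = 2 * half + 1
    for i in range(n):
        for j in range(n):
            out += k[i, j] * padded[i:i + img.shape[0], j:j + img.shape[1]]
    return np.abs(out)


def shoelace_area(vertices) -> float:
    """Polygon area from the shoelace formula; vertices as (x, y)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
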