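"""Fusion of the most-salient region with the foreground mask.

Per frame: binarize the saliency map to the connected region holding the
global maximum, AND it with the background-model foreground mask, drop
small blobs, and emit the centroid of the largest surviving blob if it
clears the detection area threshold.  The pipeline outputs at most one
candidate per frame; temporal filtering is the tracker's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .saliency import SaliencyMap

__all__ = [
    "FusionConfig",
    "Blob",
    "Detection",
    "most_salient_region",
    "fuse",
    "extract_detection",
    "detect_frame",
]


@dataclass(frozen=True)
class FusionConfig:
    min_blob_area: int = 5            # blobs below this are noise, removed
    detection_area_threshold: int = 30  # largest blob must reach this to count
    binarize_fraction: float = 0.75   # of the global saliency max
    connectivity: int = 8             # 8-connected components

    def __post_init__(self) -> None:
        if self.min_blob_area > self.detection_area_threshold:
            raise ValueError("min_blob_area must not exceed detection_area_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Blob:
    label: int
    area: int
    centroid: tuple[float, float]  # (x, y)

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("blob area must be >= 1")


@dataclass
class Detection:
    frame_index: int
    x: float
    y: float
    area: int
    source_blob: Blob | None = None


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def most_salient_region(salmap: SaliencyMap, binarize_fraction: float = 0.75,
                        connectivity: int = 8) -> np.ndarray:
    """Binary mask of the single most salient region.

    The map is thresholded at ``binarize_fraction`` of its global maximum
    and the connected component containing the maximum returned.  A
    constant (e.g. all-zero) map has no salient region: empty mask.
    """
    v = salmap.values
    if v.max() - v.min() <= 1e-12:
        return np.zeros_like(v, dtype=bool)
    supra = v >= binarize_fraction * v.max()
    labels, _ = ndimage.label(supra, structure=_structure(connectivity))
    peak = np.unravel_index(np.argmax(v), v.shape)
    return labels == labels[peak]


def fuse(foreground: np.ndarray, salient: np.ndarray) -> np.ndarray:
    """Pointwise AND of the foreground and binary saliency masks."""
    fg = np.asarray(foreground, dtype=bool)
    sal = np.asarray(salient, dtype=bool)
    if fg.shape != sal.shape:
        raise ValueError(f"mask shape mismatch: {fg.shape} vs {sal.shape}")
    return fg & sal


def extract_detection(fused: np.ndarray, cfg: FusionConfig | None = None,
                      frame_index: int = 0,
                      suppression_mask: np.ndarray | None = None) -> Detection | None:
    """Largest surviving blob of the fused mask, or None.

    Connected components below ``min_blob_area`` are removed as noise; the
    largest remaining blob becomes a detection if its area reaches
    ``detection_area_threshold``.  Ties for largest go to the blob whose
    centroid sits lower in the image (nearer the machine).  An optional
    suppression mask (e.g. labeled cooling-box regions) zeroes pixels
    before blob extraction.
    """
    cfg = cfg or FusionConfig()
    m = np.asarray(fused, dtype=bool)
    if suppression_mask is not None:
        m = m & ~np.asarray(suppression_mask, dtype=bool)
    labels, n = ndimage.label(m, structure=_structure(cfg.connectivity))
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    keep = np.flatnonzero(areas >= cfg.min_blob_area) + 1
    if keep.size == 0:
        return None
    keep_areas = areas[keep - 1]
    best_area = keep_areas.max()
    if best_area < cfg.detection_area_threshold:
        return None
    tied = keep[keep_areas == best_area]
    centroids = ndimage.center_of_mass(m, labels, tied)  # (row, col) pairs
    order = np.argsort([-c[0] for c in centroids])  # lower in image first
    lab = int(tied[order[0]])
    cy, cx = centroids[order[0]]
    blob = Blob(lab, int(best_area), (float(cx), float(cy)))
    return Detection(frame_index, float(cx), float(cy), int(best_area), blob)


def detect_frame(salmap: SaliencyMap, foreground: np.ndarray,
                 cfg: FusionConfig | None = None, frame_index: int = 0,
                 suppression_mask: np.ndarray | None = None) -> Detection | None:
    """Full fusion step for one frame: select, AND, filter, extract."""
    cfg = cfg or FusionConfig()
    salient = most_salient_region(salmap, cfg.binarize_fraction, cfg.connectivity)
    fused = fuse(foreground, salient)
    return extract_detection(fused, cfg, frame_index, suppression_mask)
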