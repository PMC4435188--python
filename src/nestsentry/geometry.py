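"""Flat-ground camera geometry.

A forward-looking camera is mounted at height ``h`` above a flat ground
plane and tilted downward by ``tilt`` degrees.  The vertical field of view
spans ``vfov`` degrees around the optical axis, so the upper image boundary
ray points ``tilt - vfov/2`` below the horizontal and the lower boundary
ray ``tilt + vfov/2``.  A ray pointing ``theta`` degrees below horizontal
intersects the ground at a distance ``h / tan(theta)`` in front of the
camera, which maps image rows to metric ground distance.

Two row models are provided:

* *linear-in-angle* (default): the ray angle varies linearly with the row
  index across the vertical field of view.  For the moderate fields of view
  used here the error relative to a true pinhole camera is a few percent,
  well inside the precision of the range figures this model is checked
  against.
* *pinhole*: the true tangent-plane projection, selectable with
  ``pinhole=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraGeometry",
    "InfiniteRangeError",
    "ground_range",
    "pixel_row_to_distance",
    "distance_to_pixel_row",
]


class InfiniteRangeError(ValueError):
    """The upper field-of-view boundary ray does not intersect the ground."""


@dataclass(frozen=True)
class CameraGeometry:
    """Extrinsics and intrinsics of the nest-scouting camera.

    Defaults describe an RGB camera mounted 0.8 m above the field on the
    front of a vehicle, tilted 20° downward, with a 43° x 34° (H x V)
    field of view, imaging at 640 x 480 after rescaling.
    """

    height_m: float = 0.8
    tilt_deg: float = 20.0
    vfov_deg: float = 34.0
    hfov_deg: float = 43.0
    image_width: int = 640
    image_height: int = 480
    pinhole: bool = False

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError(f"camera height must be positive, got {self.height_m}")
        if self.vfov_deg < 0 or self.hfov_deg < 0:
            raise ValueError("fields of view must be non-negative")
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image dimensions must be at least 1 pixel")
        if self.tilt_deg - self.vfov_deg / 2.0 <= 0:
            raise InfiniteRangeError(
                "top boundary ray at or above horizontal: "
                f"tilt {self.tilt_deg}° - vfov/2 {self.vfov_deg / 2.0}° <= 0"
            )

    @property
    def top_angle_deg(self) -> float:
        """Depression angle of the upper field-of-view boundary ray."""
        return self.tilt_deg - self.vfov_deg / 2.0

    @property
    def bottom_angle_deg(self) -> float:
        """Depression angle of the lower field-of-view boundary ray."""
        return self.tilt_deg + self.vfov_deg / 2.0


def ground_range(geom: CameraGeometry) -> tuple[float, float]:
    """Near and far ground intersection distances of the imaging footprint.

    Returns ``(near_m, far_m)`` where ``near = h / tan(tilt + vfov/2)`` and
    ``far = h / tan(tilt - vfov/2)``.
    """
    near = geom.height_m / math.tan(math.radians(geom.bottom_angle_deg))
    far = geom.height_m / math.tan(math.radians(geom.top_angle_deg))
    return near, far


def _row_to_angle_deg(row, geom: CameraGeometry):
    """Depression angle of the ray through image row(s), top row = 0."""
    h = geom.image_height
    frac = np.asarray(row, dtype=float) / (h - 1) if h > 1 else np.zeros_like(
        np.asarray(row, dtype=float)
    )
    if geom.pinhole:
        # true tangent-plane model: focal length from the vertical FOV
        half = math.radians(geom.vfov_deg / 2.0)
        f = ((h - 1) / 2.0) / math.tan(half) if half > 0 else math.inf
        dy = np.asarray(row, dtype=float) - (h - 1) / 2.0
        return geom.tilt_deg + np.degrees(np.arctan2(dy, f))
    return geom.top_angle_deg + geom.vfov_deg * frac


def pixel_row_to_distance(row, geom: CameraGeometry):
    """Ground distance (m) of the flat-ground point imaged at ``row``.

    ``row`` may be a scalar or array; rows are counted from the top of the
    image, so row 0 maps to the far range limit and the bottom row to the
    near limit.  Rows outside ``[0, image_height)`` raise ``ValueError``.
    """
    r = np.asarray(row)
    if np.any(r < 0) or np.any(r >= geom.image_height):
        raise ValueError(
            f"row index out of range [0, {geom.image_height}): {row!r}"
        )
    angle = _row_to_angle_deg(r, geom)
    d = geom.height_m / np.tan(np.radians(angle))
    return float(d) if np.isscalar(row) else d


def distance_to_pixel_row(distance_m, geom: CameraGeometry, *, clip: bool = False):
    """Image row imaging the flat-ground point at ``distance_m``.

    Inverse of :func:`pixel_row_to_distance` under the same row model.
    Returns a float row index (not rounded).  Distances outside the ground
    range raise ``ValueError`` unless ``clip=True``.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    near, far = ground_range(geom)
    if clip:
        d = np.clip(d, near, far)
    elif np.any(d < near - 1e-9) or np.any(d > far + 1e-9):
        raise ValueError(
            f"distance {distance_m!r} outside ground range [{near:.3f}, {far:.3f}] m"
        )
    angle = np.degrees(np.arctan2(geom.height_m, d))
    h = geom.image_height
    if geom.pinhole:
        half = math.radians(geom.vfov_deg / 2.0)
        f = ((h - 1) / 2.0) / math.tan(half) if half > 0 else math.inf
        row = (h - 1) / 2.0 + f * np.tan(np.radians(angle - geom.tilt_deg))
    else:
        if geom.vfov_deg == 0:
            row = np.full_like(np.asarray(d, dtype=float), (h - 1) / 2.0)
        else:
            row = (angle - geom.top_angle_deg) / geom.vfov_deg * (h - 1)
    row = np.clip(row, 0, h - 1)
    return float(row) if np.isscalar(distance_m) else row
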