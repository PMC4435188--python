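"""Image frame container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageFrame"]


@dataclass
class ImageFrame:
    """One RGB frame of a sequence.

    ``pixels`` is an H x W x 3 float array with channel values in [0, 1];
    frames of a sequence share dimensions after rescaling.
    """

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if np.nanmin(px) < -1e-9 or np.nanmax(px) > 1 + 1e-9:
            raise ValueError("channel values must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]
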