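"""In-memory container for two-channel striated-fiber micrographs.

Channel roles follow the acquisition convention used throughout the package:
channel 0 carries the alpha-actinin (Z-line) signal and channel 1 carries the
newly-synthesized-protein (NSP) click label.  Pixel values are stored as
float64 regardless of the on-disk bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_ZLINE = 0
CHANNEL_NSP = 1


@dataclass
class FiberImage:
    """Two-channel raster plus the physical pixel pitch.

    Parameters
    ----------
    data:
        Array of shape ``(2, rows, cols)``; channel 0 = Z-lines, channel 1 = NSP.
    pixel_pitch:
        Physical size of one pixel in µm (isotropic).
    fiber_mask:
        Boolean array of shape ``(rows, cols)``; True inside the fiber.
    meta:
        Free-form provenance (resolved config, generator parameters, ...).
    """

    data: np.ndarray
    pixel_pitch: float
    fiber_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError(
                f"FiberImage requires a (channels>=2, rows, cols) array, got {self.data.shape}"
            )
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.fiber_mask is not None:
            self.fiber_mask = np.asarray(self.fiber_mask, dtype=bool)
            if self.fiber_mask.shape != self.data.shape[1:]:
                raise ValueError("fiber_mask shape does not match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def zline(self) -> np.ndarray:
        return self.data[CHANNEL_ZLINE]

    @property
    def nsp(self) -> np.ndarray:
        return self.data[CHANNEL_NSP]

    def copy(self) -> "FiberImage":
        return FiberImage(
            data=self.data.copy(),
            pixel_pitch=self.pixel_pitch,
            fiber_mask=None if self.fiber_mask is None else self.fiber_mask.copy(),
            meta=dict(self.meta),
        )
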