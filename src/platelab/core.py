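"""Shared container types for masks, mask sequences, and I-z stacks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GeometryError", "PatternMask", "MaskSequence", "IZStack"]


class GeometryError(ValueError):
    """Raised when requested geometry does not fit the field or grid."""


@dataclass
class PatternMask:
    """Boolean grid of fibrinogen-covered pixels.

    ``mask[i, j]`` is True where the pixel centre lies on a printed
    line.  ``orientation`` is the direction of the lines in degrees
    (axial, (-90, 90]); ``line_width`` and ``period`` are in um.
    """

    mask: np.ndarray
    pixel_size: float
    line_width: float
    period: float
    orientation: float

    @property
    def covered_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class MaskSequence:
    """Per-frame binary platelet masks with timestamps for one field."""

    masks: np.ndarray  # (T, ny, nx) bool
    timestamps: np.ndarray  # seconds
    pixel_size: float  # um per px

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.masks.shape[0] != self.timestamps.size:
            raise ValueError("number of frames and timestamps differ")

    def __len__(self) -> int:
        return self.masks.shape[0]


@dataclass
class IZStack:
    """Grid of I-z approach curves.

    ``current`` has shape (ny, nx, ns); samples after the per-pixel
    trigger stop are NaN.  ``z`` is the shared, strictly descending
    sample grid in nm (arbitrary origin).  Currents may be stored
    normalized to ``i_sat``.
    """

    current: np.ndarray
    z: np.ndarray
    i_sat: float
    trigger: float
    pressure_kpa: float
    pixel_size_um: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or np.any(np.diff(z) >= 0):
            raise ValueError("z must be a strictly descending 1-D grid")
        if not 0.0 < self.trigger < 1.0:
            raise ValueError("trigger must be a fraction in (0, 1)")
        if self.current.ndim != 3 or self.current.shape[2] != z.size:
            raise ValueError("current must have shape (ny, nx, ns) matching z")

    @property
    def shape(self) -> tuple[int, int]:
        return self.current.shape[:2]

    @property
    def z_step(self) -> float:
        return float(self.z[0] - self.z[1])
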