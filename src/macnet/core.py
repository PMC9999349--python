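"""Shared data containers for micrographs, skeletons and derived fields.

Conventions used throughout the package:

* images are 2D ``numpy`` arrays indexed row-major, ``[row, col]``;
* the coordinate origin sits at the *center of the top-left pixel*,
  with x increasing rightward (columns) and y downward (rows);
* physical coordinates are micrometers, times are seconds;
* angles are measured from the +x axis in radians and, where they
  describe filament/nematic orientation, are pi-periodic in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Micrograph",
    "SkeletonImage",
    "TimeSeries",
    "OrientationField",
    "QMap",
    "VelocityField",
]

_CHANNELS = ("actin", "myosin", "membrane", "other")


@dataclass
class Micrograph:
    """A single-channel 2D fluorescence image with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities (arbitrary units).
    pixel_size_um
        Edge length of one pixel in micrometers; must be positive.
    channel
        One of ``{"actin", "myosin", "membrane", "other"}``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "actin"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Micrograph.pixels must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_area_um2(self) -> float:
        """Physical field-of-view area in square micrometers."""
        return self.pixels.size * self.pixel_size_um**2


@dataclass
class SkeletonImage:
    """Binary, 1-px-wide filament map sharing a micrograph's geometry."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("SkeletonImage.mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass
class TimeSeries:
    """An ordered stack of single-channel frames at a fixed interval.

    ``t0_index`` marks the frame that defines t = 0 s (in contraction
    experiments: the frame of initial myosin binding).
    """

    frames: list[Micrograph]
    frame_interval_s: float
    t0_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("TimeSeries needs at least one frame")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        shape = self.frames[0].shape
        px = self.frames[0].pixel_size_um
        for f in self.frames:
            if f.shape != shape or f.pixel_size_um != px:
                raise ValueError("all frames must share geometry")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um

    def times_s(self) -> np.ndarray:
        """Frame times in seconds relative to ``t0_index``."""
        n = len(self.frames)
        return (np.arange(n) - self.t0_index) * self.frame_interval_s

    def as_array(self) -> np.ndarray:
        """Stack the frames into a (n_frames, H, W) array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class OrientationField:
    """Per-window dominant orientation on a coarse grid.

    ``angles`` are pi-periodic in [0, pi); ``coherence`` in [0, 1]
    measures how anisotropic the local structure tensor is; windows
    without sufficient gradient signal are flagged invalid.
    """

    window_px: int
    angles: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.angles.shape == self.coherence.shape == self.valid.shape):
            raise ValueError("angles/coherence/valid must share shape")
        if self.window_px < 1:
            raise ValueError("window_px must be positive")

    @property
    def window_um(self) -> float:
        return self.window_px * self.pixel_size_um


@dataclass
class QMap:
    """Per-window local nematic order parameter q in [-1, 1].

    Windows with too few valid neighbours within the kernel are NaN.
    """

    q: np.ndarray
    kernel: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be a positive odd integer")
        finite = self.q[np.isfinite(self.q)]
        if finite.size and (np.any(finite > 1 + 1e-9) or np.any(finite < -1 - 1e-9)):
            raise ValueError("|q| must not exceed 1")


@dataclass
class VelocityField:
    """PIV vector grid for one frame pair, in physical units.

    ``x_um``/``y_um`` give the interrogation-window centers,
    ``u_um_s``/``v_um_s`` the velocity components (x rightward,
    y downward) and ``valid`` marks vectors that passed validation.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    u_um_s: np.ndarray
    v_um_s: np.ndarray
    valid: np.ndarray
    time_s: float = 0.0

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.x_um, self.y_um, self.u_um_s, self.v_um_s, self.valid)}
        if len(shapes) != 1:
            raise ValueError("all VelocityField grids must share shape")
        self.valid = np.asarray(self.valid, dtype=bool)
        uv = np.stack([self.u_um_s[self.valid], self.v_um_s[self.valid]])
        if uv.size and not np.all(np.isfinite(uv)):
            raise ValueError("valid vectors must be finite")

    def speeds(self) -> np.ndarray:
        """Magnitudes of the valid vectors, um/s."""
        return np.hypot(self.u_um_s[self.valid], self.v_um_s[self.valid])
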