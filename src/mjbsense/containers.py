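"""Lightweight containers for PROPELLER data and reconstruction artefacts.

Arrays are plain ``numpy`` arrays; the dataclasses only bundle them with
the geometry metadata that the reconstruction needs (blade angles, blade
width, acceleration, acquired-line pattern).  Axis order is
``(blade, coil, phase-encode line, readout point)`` for k-space and
``(..., y, x)`` for images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GroundTruthImage", "CoilMaps", "MotionParams", "BladeSet"]


@dataclass
class GroundTruthImage:
    """Real-valued magnitude image used as the object being imaged."""

    pixels: np.ndarray
    fov_mm: float = 240.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("ground-truth image must be 2D and square")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ground-truth image must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("ground-truth image must be non-negative")

    @property
    def matrix_size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CoilMaps:
    """Complex receive-sensitivity fields, shape ``(n_coils, N, N)``."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 3:
            raise ValueError("coil maps must have shape (n_coils, N, N)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps must be finite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def matrix_size(self) -> int:
        return self.maps.shape[-1]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares magnitude."""
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


@dataclass
class MotionParams:
    """Per-blade in-plane rigid motion (object pose during acquisition
    relative to the reference frame).  Blade 0 is the motion reference by
    convention."""

    rotations_deg: np.ndarray
    shifts_x_px: np.ndarray
    shifts_y_px: np.ndarray

    def __post_init__(self) -> None:
        self.rotations_deg = np.atleast_1d(np.asarray(self.rotations_deg, float))
        self.shifts_x_px = np.atleast_1d(np.asarray(self.shifts_x_px, float))
        self.shifts_y_px = np.atleast_1d(np.asarray(self.shifts_y_px, float))
        n = len(self.rotations_deg)
        if len(self.shifts_x_px) != n or len(self.shifts_y_px) != n:
            raise ValueError("motion parameter arrays must share one length")
        for a in (self.rotations_deg, self.shifts_x_px, self.shifts_y_px):
            if not np.all(np.isfinite(a)):
                raise ValueError("motion parameters must be finite")

    @property
    def n_blades(self) -> int:
        return len(self.rotations_deg)

    @classmethod
    def zero(cls, n_blades: int) -> "MotionParams":
        z = np.zeros(n_blades)
        return cls(z.copy(), z.copy(), z.copy())

    def as_array(self) -> np.ndarray:
        """(n_blades, 3) array of (rotation_deg, dx_px, dy_px)."""
        return np.stack(
            [self.rotations_deg, self.shifts_x_px, self.shifts_y_px], axis=1
        )

    def relative_to_blade0(self) -> "MotionParams":
        """Subtract blade 0's parameters so the reference blade is zero."""
        return MotionParams(
            self.rotations_deg - self.rotations_deg[0],
            self.shifts_x_px - self.shifts_x_px[0],
            self.shifts_y_px - self.shifts_y_px[0],
        )


@dataclass
class BladeSet:
    """Multi-coil PROPELLER blade k-space with geometry metadata.

    ``kspace`` has shape ``(n_blades, n_coils, n_acquired_lines,
    n_readout)``.  ``blade_width_lines`` is the full pre-undersampling
    blade width W; ``acquired_line_indices`` index into the W-line band
    (band index ``w`` corresponds to the centered k-space row
    ``w - W//2``, so DC sits at band index ``W//2``).
    """

    kspace: np.ndarray
    blade_angles_deg: np.ndarray
    blade_width_lines: int
    n_readout: int
    accel_factor: int = 1
    acquired_line_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.kspace = np.asarray(self.kspace, dtype=complex)
        if self.kspace.ndim != 4:
            raise ValueError("kspace must be (blade, coil, line, readout)")
        self.blade_angles_deg = np.asarray(self.blade_angles_deg, float)
        if len(self.blade_angles_deg) != self.kspace.shape[0]:
            raise ValueError("one angle per blade required")
        if self.acquired_line_indices is None:
            self.acquired_line_indices = np.arange(self.blade_width_lines)
        self.acquired_line_indices = np.asarray(self.acquired_line_indices, int)
        if len(self.acquired_line_indices) != self.kspace.shape[2]:
            raise ValueError("acquired_line_indices must match kspace lines")
        if self.kspace.shape[3] != self.n_readout:
            raise ValueError("readout length mismatch")
        if self.blade_width_lines > self.n_readout:
            raise ValueError("blade width cannot exceed readout length")

    @property
    def n_blades(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[1]

    @property
    def n_acquired_lines(self) -> int:
        return self.kspace.shape[2]

    def copy_with(self, **kw) -> "BladeSet":
        return replace(self, **kw)
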