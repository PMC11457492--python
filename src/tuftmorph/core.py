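"""Core data containers shared across analysis stages.

Conventions
-----------
* All physical coordinates are real-valued nanometres, origin at the image /
  volume corner, x to the right, y down, z increasing from the apical surface
  into the cell.
* Pixel / voxel index (0, 0[, 0]) covers the half-open interval [0, size) nm,
  so the centre of array sample ``j`` sits at ``(j + 0.5) * pixel_size_nm``.
* 3D arrays are indexed ``[z, y, x]``; calibration triples are ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ImagePlane", "PointSet", "VolumeMask", "LineProfile"]


@dataclass
class ImagePlane:
    """A calibrated 2D grayscale image."""

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImagePlane.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImagePlane.pixels must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PointSet:
    """Calibrated 2D point coordinates (filament or bundle centres)."""

    ids: np.ndarray
    coords_nm: np.ndarray
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.coords_nm = np.atleast_2d(np.asarray(self.coords_nm, dtype=float))
        if len(self) == 0:
            self.coords_nm = self.coords_nm.reshape(0, 2)
            return
        if self.coords_nm.shape != (len(self.ids), 2):
            raise ValueError("coords_nm must be (n, 2) matching ids")
        if not np.all(np.isfinite(self.coords_nm)):
            raise ValueError("coordinates must be finite")
        if len(self) > 1:
            d, _ = cKDTree(self.coords_nm).query(self.coords_nm, k=2)
            if d[:, 1].min() < 1e-6:
                raise ValueError("duplicate points (closer than 1e-6 nm)")

    def __len__(self) -> int:
        return len(self.ids)

    def translated(self, dx_nm: float, dy_nm: float) -> "PointSet":
        return PointSet(self.ids.copy(), self.coords_nm + [dx_nm, dy_nm],
                        self.pixel_size_nm)

    def rotated(self, angle_deg: float, about_nm=(0.0, 0.0)) -> "PointSet":
        t = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        about = np.asarray(about_nm, dtype=float)
        return PointSet(self.ids.copy(),
                        (self.coords_nm - about) @ rot.T + about,
                        self.pixel_size_nm)


_CHANNELS = ("actin", "microtubule", "cell", "bundle_region")


@dataclass
class VolumeMask:
    """A calibrated 3D binary channel; z is the apicobasal axis (z=0 apical)."""

    voxels: np.ndarray
    voxel_size_nm: tuple[float, float, float]  # (x, y, z)
    channel: str = "actin"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("VolumeMask.voxels must be 3D (z, y, x)")
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != 3 or min(self.voxel_size_nm) <= 0:
            raise ValueError("voxel_size_nm must be a positive (x, y, z) triple")
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def step_nm_zyx(self) -> np.ndarray:
        """Calibration reordered to match array axes (z, y, x)."""
        sx, sy, sz = self.voxel_size_nm
        return np.array([sz, sy, sx], dtype=float)


@dataclass
class LineProfile:
    """Arclength-intensity series sampled along a drawn path."""

    arclength_um: np.ndarray
    intensity: np.ndarray
    width_px: int = 1
    normalized: bool = False

    def __post_init__(self) -> None:
        self.arclength_um = np.asarray(self.arclength_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.arclength_um.shape != self.intensity.shape:
            raise ValueError("arclength and intensity must have equal length")
        if self.arclength_um.ndim != 1 or len(self.arclength_um) < 2:
            raise ValueError("profile needs at least 2 samples")
        if self.arclength_um[0] != 0 or np.any(np.diff(self.arclength_um) <= 0):
            raise ValueError("arclength must start at 0 and strictly increase")
        if self.width_px < 1:
            raise ValueError("width_px must be a positive integer")

    def __len__(self) -> int:
        return len(self.arclength_um)

    @property
    def length_um(self) -> float:
        return float(self.arclength_um[-1])
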