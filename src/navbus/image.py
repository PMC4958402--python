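"""Shared image containers: 3D volumes, the convex-sector B-mode geometry,
and single tracked ultrasound frames."""

from __future__ import annotations


from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .transforms import RigidTransform

__all__ = ["ImageVolume", "SectorGeometry", "USFrame"]


@dataclass
class ImageVolume:
    """Axis-aligned 3D scalar grid in millimetres.

    ``voxels`` is indexed ``[ix, iy, iz]``; the world coordinate of voxel
    ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (voxel centres,
    0-based).  ``frame`` tags the coordinate frame the grid lives in (CT or
    the phantom reference).  Empty voxels in reconstructed ultrasound
    volumes are NaN.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    frame: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D voxel grid, got shape {self.voxels.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacings must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World positions (mm) of (N, 3) integer voxel indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Containing-voxel indices of (N, 3) world points (may be out of range)."""
        return np.round(
            (np.asarray(points, dtype=float) - self.origin) / self.spacing
        ).astype(int)

    def contains(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)


@dataclass(frozen=True)
class SectorGeometry:
    """Convex-sector B-mode image geometry and pixel-to-physical mapping.

    The image plane uses lateral ``x`` (mm, centred on the beam axis) and
    depth ``y`` (mm, away from the transducer apex at the origin); the
    out-of-plane coordinate is zero.  The sector spans ``angular_span_deg``
    symmetrically about the depth axis between radii ``depth_range``.  The
    60-degree span matches a convex probe scanning parallel to the
    bronchoscope shaft; depth range and pixel spacing are configurable
    acquisition settings.
    """

    angular_span_deg: float = 60.0
    depth_range: tuple[float, float] = (3.0, 50.0)
    pixel_spacing_mm: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.angular_span_deg < 180.0:
            raise ValueError(f"angular span must be in (0, 180) deg: {self.angular_span_deg}")
        r_min, r_max = self.depth_range
        if not 0.0 <= r_min < r_max:
            raise ValueError(f"need 0 <= r_min < r_max, got {self.depth_range}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def r_min(self) -> float:
        return self.depth_range[0]

    @property
    def r_max(self) -> float:
        return self.depth_range[1]

    @property
    def half_angle_rad(self) -> float:
        return np.deg2rad(self.angular_span_deg) / 2.0

    @property
    def x_extent(self) -> float:
        """Maximum |lateral| coordinate inside the sector (mm)."""
        return self.r_max * np.sin(self.half_angle_rad)

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols): rows index depth, cols index lateral position."""
        ny = int(np.ceil(self.r_max / self.pixel_spacing_mm)) + 1
        nx = 2 * int(np.ceil(self.x_extent / self.pixel_spacing_mm)) + 1
        return ny, nx

    @lru_cache(maxsize=8)
    def _pixel_coordinates_cached(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.image_shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_spacing_mm
        y = np.arange(ny) * self.pixel_spacing_mm
        xg, yg = np.meshgrid(x, y)
        xg.setflags(write=False)
        yg.setflags(write=False)
        return xg, yg

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) mm of each pixel centre, as two (rows, cols) arrays."""
        return self._pixel_coordinates_cached()

    @lru_cache(maxsize=8)
    def _sector_mask_cached(self) -> np.ndarray:
        x, y = self.pixel_coordinates()
        r = np.hypot(x, y)
        theta = np.abs(np.arctan2(x, y))
        mask = (r >= self.r_min) & (r <= self.r_max) & (theta <= self.half_angle_rad)
        mask.setflags(write=False)
        return mask

    def sector_mask(self) -> np.ndarray:
        """Boolean (rows, cols) mask of pixels inside the imaging sector."""
        return self._sector_mask_cached()

    def contains_point(self, x: float, y: float) -> bool:
        r = float(np.hypot(x, y))
        theta = abs(float(np.arctan2(x, y)))
        return self.r_min <= r <= self.r_max and theta <= self.half_angle_rad

    def pixel_index(self, x, y):
        """Fractional (row, col) image index of physical plane coords (mm)."""
        ny, nx = self.image_shape
        col = np.asarray(x) / self.pixel_spacing_mm + (nx - 1) / 2.0
        row = np.asarray(y) / self.pixel_spacing_mm
        return row, col


@dataclass
class USFrame:
    """One 2D B-mode frame with its synchronized tracked probe pose.

    ``pose`` is R_T_B: the bronchoscope-sensor pose relative to the active
    reference sensor at (nearest to) ``timestamp``.
    """

    image: np.ndarray
    geometry: SectorGeometry
    timestamp: float = 0.0
    pose: RigidTransform | None = None

    def us_points(self, in_sector_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(N, 3) US-frame coordinates (x, y, 0) of pixels and their values."""
        x, y = self.geometry.pixel_coordinates()
        if in_sector_only:
            m = self.geometry.sector_mask()
        else:
            m = np.ones_like(x, dtype=bool)
        pts = np.column_stack(
            [x[m], y[m], np.zeros(int(m.sum()))]
        )
        return pts, self.image[m]
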