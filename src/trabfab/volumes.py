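"""Voxel-grid containers used throughout the toolkit.

Grids follow the CT-stack convention: axis order is ``(slice, row, column)``
which maps to world axes ``(z, y, x)``.  ``spacing_mm`` and ``origin_mm`` are
stored in the same grid-axis order; anything that is a *point* or *direction*
in world space is an ``(x, y, z)`` triple in millimetres.  Voxel centres sit
at ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "BinaryVolume", "SphereVOI", "sphere_voxel_mask"]


def _as_triple(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape == ():
        arr = np.full(3, float(arr))
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return arr


@dataclass
class VoxelVolume:
    """A 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    grid:
        3D numeric array, axis order (slice, row, column) = world (z, y, x).
    spacing_mm:
        Per-axis voxel size in mm, grid-axis order (z, y, x). A scalar means
        isotropic voxels.
    origin_mm:
        World position of voxel (0, 0, 0), grid-axis order (z, y, x).
    value_range:
        Optional (min, max) metadata describing the nominal intensity scale.
    """

    grid: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    value_range: tuple | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("all spacing components must be > 0")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def spacing_xyz(self) -> np.ndarray:
        """Voxel spacing reordered to world (x, y, z)."""
        return self.spacing_mm[::-1]

    @property
    def origin_xyz(self) -> np.ndarray:
        return self.origin_mm[::-1]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid (z, y, x) in mm."""
        return np.asarray(self.shape) * self.spacing_mm

    def index_to_world(self, ijk) -> np.ndarray:
        """Map (fractional) grid indices (z,y,x order) to world (x,y,z) mm."""
        ijk = np.asarray(ijk, dtype=float)
        single = ijk.ndim == 1
        zyx = self.origin_mm + np.atleast_2d(ijk) * self.spacing_mm
        out = zyx[:, ::-1]
        return out[0] if single else out

    def world_to_index(self, xyz) -> np.ndarray:
        """Map world (x,y,z) mm to fractional grid indices (z,y,x order)."""
        xyz = np.asarray(xyz, dtype=float)
        single = xyz.ndim == 1
        zyx = np.atleast_2d(xyz)[:, ::-1]
        out = (zyx - self.origin_mm) / self.spacing_mm
        return out[0] if single else out

    def copy_with(self, grid=None, spacing_mm=None, origin_mm=None):
        cls = type(self)
        return cls(
            grid=self.grid.copy() if grid is None else grid,
            spacing_mm=self.spacing_mm if spacing_mm is None else spacing_mm,
            origin_mm=self.origin_mm if origin_mm is None else origin_mm,
        )


@dataclass
class BinaryVolume(VoxelVolume):
    """A segmented (bone = True) voxel grid."""

    def __post_init__(self):
        super().__post_init__()
        if self.grid.dtype != bool:
            self.grid = self.grid.astype(bool)

    @property
    def bone_fraction(self) -> float:
        """BV/TV: fraction of voxels in the bone phase."""
        return float(np.count_nonzero(self.grid)) / self.grid.size

    def to_voxel(self, bone_value: float = 255.0) -> VoxelVolume:
        return VoxelVolume(
            grid=self.grid.astype(np.float64) * bone_value,
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            value_range=(0.0, bone_value),
        )


@dataclass
class SphereVOI:
    """A spherical volume of interest: centre (x, y, z) and radius in mm."""

    center_mm: np.ndarray
    radius_mm: float

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.center_mm.shape != (3,):
            raise ValueError("center_mm must be a 3-vector (x, y, z)")
        self.radius_mm = float(self.radius_mm)
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


def sphere_voxel_mask(vol: VoxelVolume, voi: SphereVOI):
    """Boolean mask (and bounding slices) of voxel centres inside a VOI.

    Returns ``(slices, mask)`` where ``mask`` covers only the bounding box of
    the sphere intersected with the grid; voxels of the sphere that fall
    outside the grid are simply absent.
    """
    c_idx = vol.world_to_index(voi.center_mm)  # (z, y, x) fractional
    r_vox = voi.radius_mm / vol.spacing_mm  # per grid axis
    lo = np.maximum(np.floor(c_idx - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + r_vox).astype(int) + 1, np.asarray(vol.shape))
    if np.any(hi <= lo):
        slices = tuple(slice(0, 0) for _ in range(3))
        return slices, np.zeros((0, 0, 0), dtype=bool)
    slices = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [
        (np.arange(lo[a], hi[a]) - c_idx[a]) * vol.spacing_mm[a] for a in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    mask = zz * zz + yy * yy + xx * xx <= voi.radius_mm**2
    return slices, mask
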