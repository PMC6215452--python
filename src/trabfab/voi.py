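"""Spherical volume-of-interest sampling in cubic close-packed arrangement.

A cancellous region is tiled with equal-radius spheres on a face-centred
cubic lattice whose nearest-neighbour centre distance is exactly one sphere
diameter, so adjacent VOIs just touch and every piece of bone is analysed at
most once.  A VOI is retained only when (by default) at least 95% of its
voxels fall inside the supplied cancellous mask, a reproducible surrogate
for pruning VOIs that stray into cortical bone or the medullary cavity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volumes import BinaryVolume, SphereVOI, sphere_voxel_mask

__all__ = ["VOISet", "ccp_pack", "exclude_vois", "trabecular_spacing",
           "continuum_ok", "fcc_basis", "default_orientation"]

FCC_PACKING_FRACTION = np.pi / np.sqrt(18.0)


@dataclass
class VOISet:
    """Uniform-radius spherical VOIs plus the lattice that generated them."""

    vois: list
    radius_mm: float
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    offset_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    containment_frac: np.ndarray | None = None

    def __len__(self):
        return len(self.vois)

    def centers(self) -> np.ndarray:
        if not self.vois:
            return np.zeros((0, 3))
        return np.stack([v.center_mm for v in self.vois])


def fcc_basis(radius_mm: float) -> np.ndarray:
    """Primitive FCC lattice vectors (rows, world xyz) with nearest-neighbour
    distance ``2 * radius_mm``: a/2*(0,1,1), a/2*(1,0,1), a/2*(1,1,0) with
    cubic cell edge a = 2*sqrt(2)*r."""
    a = 2.0 * np.sqrt(2.0) * radius_mm
    return (a / 2.0) * np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])


def default_orientation() -> np.ndarray:
    """Rotation taking the cubic [111] direction onto +z, so close-packed
    layers stack along the slice axis."""
    z = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    x = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    y = np.cross(z, x)
    # rows of R map lattice coordinates into world (x, y, z)
    return np.stack([x, y, z])


def ccp_pack(mask: BinaryVolume, radius_mm: float, offset_mm=(0.0, 0.0, 0.0),
             orientation: np.ndarray | None = None,
             containment: float = 0.95) -> VOISet:
    """Tile a mask with touching spheres on an FCC lattice.

    The lattice is anchored at the mask centroid plus ``offset_mm`` and
    rotated by ``orientation`` (default: [111] stacking along z).  A sphere
    is retained when at least ``containment`` of its voxels lie inside the
    mask (sphere voxels outside the image count against containment).
    """
    if radius_mm < 2 * float(np.min(mask.spacing_mm)):
        raise ValueError("VOI radius must be at least 2 voxels")
    R = default_orientation() if orientation is None else np.asarray(orientation, float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ValueError("orientation must be orthonormal")
    basis = fcc_basis(radius_mm) @ R.T  # world-frame lattice vectors (rows)

    if mask.grid.any():
        com_idx = np.array(ndi.center_of_mass(mask.grid))
        anchor = mask.index_to_world(com_idx)
    else:
        anchor = mask.index_to_world((np.asarray(mask.shape) - 1) / 2.0)
    anchor = np.asarray(anchor, float) + np.asarray(offset_mm, float)

    # integer ranges covering the grid bounding box (plus one sphere margin)
    lo_w = mask.index_to_world(np.zeros(3)) - radius_mm
    hi_w = mask.index_to_world(np.asarray(mask.shape) - 1.0) + radius_mm
    corners = np.array([[lo_w[i] if b & (1 << i) == 0 else hi_w[i] for i in range(3)]
                        for b in range(8)])
    n_coords = np.linalg.solve(basis.T, (corners - anchor).T).T
    n_lo = np.floor(n_coords.min(axis=0)).astype(int) - 1
    n_hi = np.ceil(n_coords.max(axis=0)).astype(int) + 1

    vois, fracs = [], []
    for n0 in range(n_lo[0], n_hi[0] + 1):
        for n1 in range(n_lo[1], n_hi[1] + 1):
            for n2 in range(n_lo[2], n_hi[2] + 1):
                c = anchor + n0 * basis[0] + n1 * basis[1] + n2 * basis[2]
                voi = SphereVOI(center_mm=c, radius_mm=radius_mm)
                frac = containment_fraction(mask, voi)
                if frac >= containment:
                    vois.append(voi)
                    fracs.append(frac)
    if not vois:
        warnings.warn("mask too small for any VOI at this radius", stacklevel=2)
    return VOISet(vois=vois, radius_mm=radius_mm, orientation=R,
                  offset_mm=np.asarray(offset_mm, float),
                  containment_frac=np.asarray(fracs))


def containment_fraction(mask: BinaryVolume, voi: SphereVOI) -> float:
    """Fraction of a VOI's voxels lying in the mask (voxels outside the image
    count as outside the mask)."""
    n_total_expected = None
    slices, sph = sphere_voxel_mask(mask, voi)
    n_in_grid = int(np.count_nonzero(sph))
    if n_in_grid == 0:
        return 0.0
    # total sphere voxels irrespective of clipping at the image border
    r_vox = voi.radius_mm / mask.spacing_mm
    ax = [np.arange(-int(np.ceil(r)), int(np.ceil(r)) + 1) * s
          for r, s in zip(r_vox, mask.spacing_mm)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=True)
    n_total_expected = int(np.count_nonzero(zz * zz + yy * yy + xx * xx
                                            <= voi.radius_mm**2))
    n_bone = int(np.count_nonzero(mask.grid[slices] & sph))
    return n_bone / n_total_expected


def exclude_vois(vois: VOISet, exclusion_mask: BinaryVolume,
                 max_excluded_frac: float = 0.0) -> VOISet:
    """Drop VOIs overlapping an exclusion mask (cracks, deformed regions)
    by more than ``max_excluded_frac`` of their volume."""
    kept, fracs = [], []
    for i, voi in enumerate(vois.vois):
        slices, sph = sphere_voxel_mask(exclusion_mask, voi)
        n_sph = int(np.count_nonzero(sph))
        n_bad = int(np.count_nonzero(exclusion_mask.grid[slices] & sph)) if n_sph else 0
        frac = n_bad / n_sph if n_sph else 0.0
        if frac <= max_excluded_frac:
            kept.append(voi)
            if vois.containment_frac is not None and len(vois.containment_frac) == len(vois.vois):
                fracs.append(vois.containment_frac[i])
    return VOISet(vois=kept, radius_mm=vois.radius_mm, orientation=vois.orientation,
                  offset_mm=vois.offset_mm,
                  containment_frac=np.asarray(fracs) if fracs else None)


def trabecular_spacing(binary: BinaryVolume, region: SphereVOI | None = None,
                       n_bins: int = 40) -> float:
    """Mean trabecular spacing (Tb.Sp): mean local thickness of the
    background phase, with thickness defined by the largest inscribed sphere.

    The Euclidean distance transform of the background gives, at each
    background voxel, the radius of the largest sphere centred there; the
    local-thickness map assigns every voxel the diameter of the largest such
    sphere that covers it (computed here with radius binning, bin width well
    under a voxel for typical geometries).
    """
    bg = ~binary.grid
    if region is not None:
        slices, sph = sphere_voxel_mask(binary, region)
        sel = np.zeros_like(bg)
        sel[slices] = sph
    else:
        sel = np.ones_like(bg)
    fg_in = binary.grid & sel
    bg_in = bg & sel
    if not fg_in.any() or not bg_in.any():
        raise ValueError("region must contain both bone and background phases")

    spacing = binary.spacing_mm
    dist = ndi.distance_transform_edt(bg, sampling=spacing)
    rmax = float(dist.max())
    if rmax == 0:
        raise ValueError("background phase has zero thickness")
    edges = np.linspace(0.0, rmax, n_bins + 1)
    thickness = np.zeros_like(dist)
    iso = float(np.min(spacing))
    for b in range(n_bins - 1, -1, -1):
        r_lo, r_hi = edges[b], edges[b + 1]
        centers = (dist > r_lo) & (dist <= r_hi)
        if not centers.any():
            continue
        r_rep = 0.5 * (r_lo + r_hi)
        # voxels within r_rep of any centre in this bin
        cover_dist = ndi.distance_transform_edt(~centers, sampling=spacing)
        newly = (cover_dist <= r_rep) & (thickness == 0) & bg
        thickness[newly] = 2.0 * max(r_rep, iso / 2.0)
    vals = thickness[bg_in]
    vals = vals[vals > 0]
    return float(vals.mean())


def continuum_ok(voi: SphereVOI, tb_sp_mm: float, factor: float = 5.0) -> bool:
    """Continuum-scale rule: the VOI diameter must span at least ``factor``
    (default 5) mean trabecular spacings."""
    if tb_sp_mm <= 0:
        raise ValueError("tb_sp_mm must be > 0")
    return 2.0 * voi.radius_mm >= factor * tb_sp_mm
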