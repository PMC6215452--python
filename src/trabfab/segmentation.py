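"""CT-stack segmentation: local thresholding, floating-voxel cleaning,
isotropic resampling, and median-difference background subtraction.

Four protocols are implemented, matching the kind of input each targets:

1. high-contrast micro-CT: Bernsen local thresholding + floating-voxel
   removal;
2. medical CT with anisotropic voxels: isotropic upsampling (in-plane by a
   multiplier m, axially by m*f where f = slice thickness / pixel
   resolution), then protocol 1;
3. peripheral-QCT-like data (slices thinner than pixels): in-plane-only
   resampling, a small 3D median denoise, then protocol 1;
4. noisy low-voltage scans: small-radius 3D median (high-frequency denoise)
   minus successive large-radius 2D medians (background estimate), small 3D
   mean smoothing, then a global high-pass threshold.

All filter windows are discrete balls of the stated radius; borders are
handled by edge replication so constants are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volumes import BinaryVolume, VoxelVolume

__all__ = [
    "ResampleSpec",
    "ProtocolSpec",
    "ball_footprint",
    "bernsen_threshold",
    "remove_floating",
    "resample_isotropic",
    "background_subtract",
    "mean_filter",
    "run_protocol",
    "dice",
]


@dataclass
class ResampleSpec:
    """Resampling geometry for anisotropic CT stacks.

    ``f = slice_thickness / pixel_resolution``; the in-plane axes are
    upsampled by ``upsample_multiplier`` and the axial axis by
    ``upsample_multiplier * f`` so the output voxels are isotropic at
    ``pixel_resolution / upsample_multiplier``.
    """

    pixel_resolution_mm: float
    slice_thickness_mm: float
    upsample_multiplier: int = 3

    def __post_init__(self):
        if self.pixel_resolution_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("resolutions must be > 0")
        if self.upsample_multiplier < 1:
            raise ValueError("upsample_multiplier must be >= 1")

    @property
    def f(self) -> float:
        return self.slice_thickness_mm / self.pixel_resolution_mm

    @property
    def axial_factor(self) -> float:
        return self.upsample_multiplier * self.f


@dataclass
class ProtocolSpec:
    """Parameters of one segmentation protocol (ids 1-4)."""

    protocol: int
    window_radius_px: int = 5
    contrast_threshold: float = 30.0
    median3d_radius_px: int = 2
    background_median_radius_px: int = 10
    mean3d_radius_px: int = 2
    global_threshold: float | None = None
    upsample_multiplier: int = 3

    def __post_init__(self):
        if self.protocol not in (1, 2, 3, 4):
            raise ValueError("protocol must be 1-4 (protocol 5 is qualitative-only)")
        for name in ("window_radius_px", "median3d_radius_px",
                     "background_median_radius_px", "mean3d_radius_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be >= 0")


def ball_footprint(radius: int) -> np.ndarray:
    """Discrete ball: voxels whose centre lies within ``radius`` of the origin."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    return zz * zz + yy * yy + xx * xx <= r * r


def _disk_footprint(axis: int, radius: int) -> np.ndarray:
    """2D disk footprint embedded in 3D, normal to the given grid axis."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    a, b = np.meshgrid(ax, ax, indexing="ij", sparse=True)
    disk = a * a + b * b <= r * r
    shape = [1, 1, 1]
    plane = [i for i in range(3) if i != axis]
    shape[plane[0]] = 2 * r + 1
    shape[plane[1]] = 2 * r + 1
    return np.reshape(disk, shape)


def bernsen_threshold(vol: VoxelVolume, window_radius_px: int = 5,
                      contrast_threshold: float = 30.0) -> BinaryVolume:
    """Bernsen local thresholding.

    A voxel is bone iff the local contrast (max - min over the window ball)
    reaches ``contrast_threshold`` *and* its value exceeds the local
    mid-grey.  Low-contrast windows are assigned to background, which is
    what keeps uniform dense non-bone material (e.g. dried marrow) out of
    the bone phase.
    """
    if window_radius_px < 1:
        raise ValueError("window_radius_px must be >= 1")
    g = np.asarray(vol.grid, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("input volume contains non-finite voxels")
    fp = ball_footprint(window_radius_px)
    gmax = ndi.maximum_filter(g, footprint=fp, mode="nearest")
    gmin = ndi.minimum_filter(g, footprint=fp, mode="nearest")
    contrast = gmax - gmin
    mid = 0.5 * (gmax + gmin)
    bone = (contrast >= contrast_threshold) & (g > mid)
    return BinaryVolume(grid=bone, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def remove_floating(binary: BinaryVolume) -> BinaryVolume:
    """Keep only the largest 26-connected foreground component.

    Cancellous bone forms a single connected network, so isolated
    ('floating') voxels are segmentation noise.  Never adds voxels; raises
    on an empty foreground.
    """
    labels, n = ndi.label(binary.grid, structure=_CONN26)
    if n == 0:
        raise ValueError("empty foreground: nothing to clean")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))  # first-encountered label wins ties
    return BinaryVolume(grid=labels == keep, spacing_mm=binary.spacing_mm,
                        origin_mm=binary.origin_mm)


def resample_isotropic(vol: VoxelVolume, spec: ResampleSpec) -> VoxelVolume:
    """Upsample a stack to isotropic voxels with 3D cubic interpolation.

    For ``f >= 1`` (slices thicker than pixels) the in-plane axes are scaled
    by the multiplier m and the axial axis by ``m * f``.  For ``f < 1``
    (slices thinner than pixels) only the in-plane axes are resampled, down
    to the slice thickness, which already yields isotropic voxels.
    """
    m = spec.upsample_multiplier
    if spec.f >= 1.0:
        factors = (spec.axial_factor, float(m), float(m))
        out_spacing = spec.pixel_resolution_mm / m
    else:
        inplane = 1.0 / spec.f  # pixel_resolution / slice_thickness
        factors = (1.0, inplane, inplane)
        out_spacing = spec.slice_thickness_mm
    g = np.asarray(vol.grid, dtype=np.float64)
    out = ndi.zoom(g, factors, order=3, mode="nearest", grid_mode=True)
    return VoxelVolume(grid=out, spacing_mm=out_spacing, origin_mm=vol.origin_mm,
                       value_range=vol.value_range)


def background_subtract(vol: VoxelVolume, small_radius_px: int = 2,
                        large_radius_px: int = 10) -> VoxelVolume:
    """Median-difference background subtraction.

    ``median3D_small(vol) - median2D_large(vol)`` where the large-radius 2D
    median is applied successively in all three grid directions to build a
    low-frequency background estimate.  The small median suppresses impulse
    noise; the subtraction removes smooth drift.  Negative values are
    clipped to zero.
    """
    if small_radius_px >= large_radius_px:
        raise ValueError("small_radius_px must be < large_radius_px")
    if 2 * large_radius_px + 1 > min(vol.shape[1:]) or 2 * small_radius_px + 1 > min(vol.shape):
        raise ValueError("filter radius exceeds the volume extent")
    g = np.asarray(vol.grid, dtype=np.float64)
    high = ndi.median_filter(g, footprint=ball_footprint(small_radius_px), mode="nearest")
    low = g
    for axis in range(3):
        low = ndi.median_filter(low, footprint=_disk_footprint(axis, large_radius_px),
                                mode="nearest")
    out = np.clip(high - low, 0.0, None)
    return VoxelVolume(grid=out, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


def mean_filter(vol: VoxelVolume, radius_px: int = 2) -> VoxelVolume:
    """3D mean filter over a ball window (edge-replicated)."""
    fp = ball_footprint(radius_px).astype(np.float64)
    fp /= fp.sum()
    out = ndi.convolve(np.asarray(vol.grid, dtype=np.float64), fp, mode="nearest")
    return VoxelVolume(grid=out, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


def median_filter3d(vol: VoxelVolume, radius_px: int = 2) -> VoxelVolume:
    """3D median filter over a ball window (edge-replicated)."""
    out = ndi.median_filter(np.asarray(vol.grid, dtype=np.float64),
                            footprint=ball_footprint(radius_px), mode="nearest")
    return VoxelVolume(grid=out, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


def _safe_remove_floating(binary: BinaryVolume) -> BinaryVolume:
    if not binary.grid.any():
        warnings.warn("segmentation produced an empty foreground", stacklevel=3)
        return binary
    return remove_floating(binary)


def _auto_global_threshold(g: np.ndarray, mask: np.ndarray | None) -> float:
    """High-pass threshold for protocol 4's final global segmentation.

    Half the bright-tail level (99.9th percentile) of the smoothed,
    background-subtracted image, floored at 2 grey values so a structure-free
    volume (noise only, residuals near zero after the median difference)
    yields an essentially empty segmentation.
    """
    vals = g[mask] if mask is not None else g
    if vals.size == 0:
        return 2.0
    return max(2.0, 0.5 * float(np.percentile(vals, 99.9)))


def run_protocol(vol: VoxelVolume, spec: ProtocolSpec,
                 mask: BinaryVolume | None = None) -> BinaryVolume:
    """Execute one of the segmentation protocols end to end."""
    mask_grid = None if mask is None else mask.grid

    if spec.protocol == 2:
        rs = ResampleSpec(
            pixel_resolution_mm=float(vol.spacing_mm[1]),
            slice_thickness_mm=float(vol.spacing_mm[0]),
            upsample_multiplier=spec.upsample_multiplier,
        )
        vol = resample_isotropic(vol, rs)
        mask_grid = None  # mask geometry no longer matches after resampling
    elif spec.protocol == 3:
        if vol.spacing_mm[0] != vol.spacing_mm[1]:
            rs = ResampleSpec(
                pixel_resolution_mm=float(vol.spacing_mm[1]),
                slice_thickness_mm=float(vol.spacing_mm[0]),
                upsample_multiplier=1,
            )
            vol = resample_isotropic(vol, rs)
            mask_grid = None
        vol = median_filter3d(vol, spec.median3d_radius_px)

    if spec.protocol in (1, 2, 3):
        seg = bernsen_threshold(vol, spec.window_radius_px, spec.contrast_threshold)
    else:  # protocol 4
        sub = background_subtract(vol, spec.median3d_radius_px,
                                  spec.background_median_radius_px)
        smooth = mean_filter(sub, spec.mean3d_radius_px)
        thr = spec.global_threshold
        if thr is None:
            thr = _auto_global_threshold(smooth.grid, mask_grid)
        seg = BinaryVolume(grid=smooth.grid >= thr, spacing_mm=vol.spacing_mm,
                           origin_mm=vol.origin_mm)

    if mask_grid is not None:
        seg = BinaryVolume(grid=seg.grid & mask_grid, spacing_mm=seg.spacing_mm,
                           origin_mm=seg.origin_mm)
    return _safe_remove_floating(seg)


def dice(a: BinaryVolume | np.ndarray, b: BinaryVolume | np.ndarray) -> float:
    """Dice overlap coefficient between two binary volumes."""
    ga = a.grid if isinstance(a, BinaryVolume) else np.asarray(a, dtype=bool)
    gb = b.grid if isinstance(b, BinaryVolume) else np.asarray(b, dtype=bool)
    inter = np.count_nonzero(ga & gb)
    denom = np.count_nonzero(ga) + np.count_nonzero(gb)
    return 1.0 if denom == 0 else 2.0 * inter / denom
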