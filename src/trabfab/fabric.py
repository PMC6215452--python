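"""Fabric-tensor estimation from directional intercept measurements.

Two directional measures are provided: the star volume distribution (SVD) —
point-sampled intercept lengths cubed, averaged over points sampled in the
bone phase — and the mean intercept length (MIL) over parallel line grids.
Either yields a scalar v(n) per test direction; a second-rank fabric tensor
is then obtained by least-squares fitting of the orientation quadric
``n . M . n = 1 / v(n)^2`` and taking ``H = M^(-1/2)`` (trace-normalised to
3), the standard MIL-ellipsoid convention.  Eigenvalues e1 >= e2 >= e3 give
the principal fabric magnitudes, their eigenvectors u1..u3 the principal
directions, and DA = e1/e3 the degree of anisotropy.

Directions follow the whole-bone analysis defaults: 2,049 quasi-uniform
orientations (Fibonacci hemisphere lattice under a seeded random rotation)
sampled at 4,000 points within the bone phase of each VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import _raycast
from .volumes import BinaryVolume, SphereVOI, sphere_voxel_mask

__all__ = [
    "DirectionSet",
    "DirectionalMeasure",
    "FabricResult",
    "FabricParams",
    "sample_directions",
    "star_sample",
    "mil_measure",
    "fit_fabric_tensor",
    "batch_fabric",
]


@dataclass
class DirectionSet:
    """Antipodally unique unit directions (world xyz rows) and the random
    rotation that was applied to the base Fibonacci lattice."""

    vectors: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")

    def __len__(self):
        return len(self.vectors)


@dataclass
class DirectionalMeasure:
    """Per-direction scalar measure (mm) plus bookkeeping."""

    directions: DirectionSet
    values: np.ndarray  # the length scale used for tensor fitting, mm
    method: str  # "svd" or "mil"
    mean_l: np.ndarray | None = None
    mean_l3: np.ndarray | None = None
    censored_frac: np.ndarray | None = None
    censored_flag: np.ndarray | None = None
    n_points: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("directional values must be positive and finite")


@dataclass
class FabricResult:
    """Symmetric positive-definite fabric tensor and its eigensystem.

    ``tensor`` is trace-normalised to 3 (isotropy = identity); eigenvalues
    are descending; eigenvectors are rows u1, u2, u3 with a deterministic
    sign convention (largest-magnitude component positive)."""

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    method: str
    n_directions: int
    n_points: int | None = None

    @property
    def da(self) -> float:
        return float(self.eigenvalues[0] / self.eigenvalues[2])

    @property
    def u1(self) -> np.ndarray:
        return self.eigenvectors[0]

    @property
    def u2(self) -> np.ndarray:
        return self.eigenvectors[1]

    @property
    def u3(self) -> np.ndarray:
        return self.eigenvectors[2]


@dataclass
class FabricParams:
    """Batch-analysis parameters (defaults are the whole-bone study values)."""

    method: str = "svd"
    n_directions: int = 2049
    n_points: int = 4000
    grid_spacing_mm: float | None = None
    seed: int | None = None


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (golden-angle spiral)."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def sample_directions(n: int = 2049, seed: int | None = None) -> DirectionSet:
    """Quasi-uniform antipodally unique direction set with a seeded random
    rigid rotation (so no direction is privileged by the lattice axes)."""
    if n < 50:
        raise ValueError("need at least 50 directions")
    base = fibonacci_hemisphere(n)
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    return DirectionSet(vectors=base @ R.T, rotation=R)


def _bone_points_in_voi(binary: BinaryVolume, voi: SphereVOI):
    slices, sph = sphere_voxel_mask(binary, voi)
    sub = binary.grid[slices] & sph
    idx = np.argwhere(sub)
    if idx.size == 0:
        raise ValueError("VOI contains no bone phase")
    offset = np.array([s.start for s in slices])
    return idx + offset


def star_sample(binary: BinaryVolume, voi: SphereVOI, dirs: DirectionSet,
                n_points: int = 4000, seed: int | None = None) -> DirectionalMeasure:
    """Star volume distribution sampling.

    Casts a bidirectional ray along every test direction from each of
    ``n_points`` voxels sampled uniformly from the bone phase inside the
    VOI (with replacement when fewer bone voxels exist), measuring the
    uninterrupted bone intercept length through the point, censored at the
    VOI sphere boundary.  Returns per-direction mean L and mean L^3; the
    directional value used for tensor fitting is (mean L^3)^(1/3), the star
    length scale, which makes SVD and MIL commensurable.
    """
    bone_idx = _bone_points_in_voi(binary, voi)
    if len(bone_idx) < 10:
        raise ValueError(f"only {len(bone_idx)} bone voxels in VOI; need >= 10")
    rng = np.random.default_rng(seed)
    replace = len(bone_idx) < n_points
    pick = rng.choice(len(bone_idx), size=n_points, replace=replace)
    pts_idx = bone_idx[pick].astype(np.float64)

    spacing = binary.spacing_mm
    step = 0.5 * float(np.min(spacing))
    d_world = dirs.vectors  # (nd, 3) xyz
    # per-step index increments (z, y, x)
    dirs_idx = np.empty_like(d_world)
    dirs_idx[:, 0] = step * d_world[:, 2] / spacing[0]
    dirs_idx[:, 1] = step * d_world[:, 1] / spacing[1]
    dirs_idx[:, 2] = step * d_world[:, 0] / spacing[2]

    pts_world = binary.index_to_world(pts_idx)  # (np, 3) xyz
    u = pts_world - voi.center_mm
    off_c = np.einsum("ij,ij->i", u, u)
    dot_dc = u @ d_world.T

    nd = len(d_world)
    mean_l = np.empty(nd)
    mean_l3 = np.empty(nd)
    cens = np.empty(nd)
    _raycast.star_lengths(
        np.ascontiguousarray(binary.grid.astype(np.uint8)),
        np.ascontiguousarray(spacing),
        np.ascontiguousarray(pts_idx),
        np.ascontiguousarray(off_c),
        np.ascontiguousarray(dirs_idx),
        np.ascontiguousarray(dot_dc),
        voi.radius_mm**2, step, mean_l, mean_l3, cens,
    )
    return DirectionalMeasure(
        directions=dirs, values=np.cbrt(mean_l3), method="svd",
        mean_l=mean_l, mean_l3=mean_l3, censored_frac=cens, n_points=n_points,
    )


def mil_measure(binary: BinaryVolume, voi: SphereVOI, dirs: DirectionSet,
                grid_spacing_mm: float | None = None,
                min_run_vox: float = 1.0) -> DirectionalMeasure:
    """Mean intercept length over a parallel-line grid per direction.

    MIL(n) = total bone length along the lines / number of bone intercepts
    (equivalently total line length * BV/TV / intersection pairs).
    Intercepts shorter than ``min_run_vox`` voxels are below the grid
    resolution (staircase fragments of lines grazing a voxelised surface)
    and are excluded from both numerator and denominator.  A direction
    whose line grid meets no bone is censored to the VOI diameter and
    flagged.
    """
    spacing = binary.spacing_mm
    vox = float(np.min(spacing))
    if grid_spacing_mm is None:
        grid_spacing_mm = 2.0 * vox
    if grid_spacing_mm < vox:
        raise ValueError("grid_spacing_mm must be >= the voxel size")
    step = 0.5 * vox
    grid8 = np.ascontiguousarray(binary.grid.astype(np.uint8))
    c_idx = np.ascontiguousarray(binary.world_to_index(voi.center_mm))
    n_half = int(np.ceil(voi.radius_mm / grid_spacing_mm))

    nd = len(dirs)
    mil = np.empty(nd)
    flags = np.empty(nd, dtype=np.int64)
    out1 = np.empty(1)
    outf = np.empty(1, dtype=np.int64)
    for j, d in enumerate(dirs.vectors):
        e1, e2 = _plane_basis(d)
        mil_dir_step = _idx_step(d, spacing, step)
        e1_idx = _idx_step(e1, spacing, grid_spacing_mm)
        e2_idx = _idx_step(e2, spacing, grid_spacing_mm)
        _raycast.mil_lines(grid8, mil_dir_step, c_idx, e1_idx, e2_idx,
                           voi.radius_mm, grid_spacing_mm, step, n_half,
                           min_run_vox * vox, out1, outf)
        mil[j] = out1[0]
        flags[j] = outf[0]
    return DirectionalMeasure(directions=dirs, values=mil, method="mil",
                              censored_flag=flags)


def _plane_basis(d: np.ndarray):
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _idx_step(v_world: np.ndarray, spacing: np.ndarray, scale: float) -> np.ndarray:
    """Index-space (z,y,x) increment corresponding to ``scale * v_world``."""
    return np.ascontiguousarray(
        np.array([scale * v_world[2] / spacing[0],
                  scale * v_world[1] / spacing[1],
                  scale * v_world[0] / spacing[2]])
    )


def fit_fabric_tensor(measure: DirectionalMeasure) -> FabricResult:
    """Least-squares orientation-quadric fit of a fabric tensor.

    Solves ``n . M . n = 1 / v(n)^2`` for the symmetric tensor M, then
    ``H = M^(-1/2)`` so that H's eigenvalues equal the directional measure
    along its principal axes.  H is trace-normalised to 3, its eigenvalues
    sorted descending, and eigenvector signs fixed so the largest-magnitude
    component is positive.
    """
    n = measure.directions.vectors
    if len(n) < 6:
        raise ValueError("need at least 6 independent directions")
    v = measure.values
    b = 1.0 / (v * v)
    A = np.column_stack([
        n[:, 0] ** 2, n[:, 1] ** 2, n[:, 2] ** 2,
        2 * n[:, 0] * n[:, 1], 2 * n[:, 0] * n[:, 2], 2 * n[:, 1] * n[:, 2],
    ])
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    M = np.array([
        [coef[0], coef[3], coef[4]],
        [coef[3], coef[1], coef[5]],
        [coef[4], coef[5], coef[2]],
    ])
    lam, vec = np.linalg.eigh(M)
    if np.any(lam <= 0):
        quad = np.einsum("ij,jk,ik->i", n, M, n)
        worst = np.argsort(quad)[:3]
        raise ValueError(
            "quadric fit is not positive definite; most offending directions: "
            f"{np.round(n[worst], 3).tolist()}"
        )
    H = (vec * lam**-0.5) @ vec.T
    H *= 3.0 / np.trace(H)
    ev, evec = np.linalg.eigh(H)
    order = np.argsort(ev)[::-1]
    ev = ev[order]
    evec = evec[:, order].T  # rows u1, u2, u3

    # deterministic handling of (near-)degenerate eigenvalues and signs
    for i in range(3):
        u = evec[i]
        k = int(np.argmax(np.abs(u)))
        if u[k] < 0:
            evec[i] = -u
    recon = (evec.T * ev) @ evec
    if not np.allclose(recon, H, atol=1e-10):
        raise AssertionError("eigen-decomposition failed to reconstruct tensor")
    return FabricResult(tensor=H, eigenvalues=ev, eigenvectors=evec,
                        method=measure.method, n_directions=len(n),
                        n_points=measure.n_points)


def batch_fabric(binary: BinaryVolume, vois, params: FabricParams | None = None) -> pd.DataFrame:
    """One fabric tensor per VOI; per-VOI failures are recorded, not raised.

    Each VOI gets its own direction-set rotation and point sample, derived
    deterministically from ``params.seed`` and the VOI index.
    """
    params = params or FabricParams()
    rows = []
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(vois.vois) * 2)
    for i, voi in enumerate(vois.vois):
        row = {
            "voi_id": i,
            "cx_mm": voi.center_mm[0], "cy_mm": voi.center_mm[1],
            "cz_mm": voi.center_mm[2], "radius_mm": voi.radius_mm,
            "method": params.method, "ok": True, "error": "",
        }
        try:
            dseed = int(children[2 * i].generate_state(1)[0] % (2**31))
            pseed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
            dirs = sample_directions(params.n_directions, seed=dseed)
            if params.method == "svd":
                meas = star_sample(binary, voi, dirs, n_points=params.n_points,
                                   seed=pseed)
            elif params.method == "mil":
                meas = mil_measure(binary, voi, dirs,
                                   grid_spacing_mm=params.grid_spacing_mm)
            else:
                raise ValueError(f"unknown method {params.method!r}")
            fab = fit_fabric_tensor(meas)
            row.update({
                "e1": fab.eigenvalues[0], "e2": fab.eigenvalues[1],
                "e3": fab.eigenvalues[2], "DA": fab.da,
            })
            for name, u in zip(("u1", "u2", "u3"), fab.eigenvectors):
                row.update({f"{name}x": u[0], f"{name}y": u[1], f"{name}z": u[2]})
            if meas.censored_frac is not None:
                row["censored_frac"] = float(np.mean(meas.censored_frac))
        except (ValueError, AssertionError) as exc:
            row["ok"] = False
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
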