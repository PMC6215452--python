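"""Synthetic trabecular phantoms with known ground truth.

Every generator here produces inputs for the downstream pipeline stages —
binary trabecular volumes with controlled fabric, greyscale pseudo-CT with
the impulse-plus-drift noise regime that the fossil-scan segmentation
protocol targets, whole-bone phantoms with known long axis and condyle
centres, rater score tables with prescribed variance components, and
bivariate allometry samples.  All randomness comes from one explicit,
per-call ``numpy`` generator seeded by the caller; outputs are bit-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volumes import BinaryVolume, VoxelVolume, _as_triple

__all__ = [
    "PhantomTruth",
    "make_rod_lattice",
    "make_plate_stack",
    "make_isotropic_boolean",
    "corrupt_ct",
    "make_bone_phantom",
    "condyle_surface_points",
    "make_score_table",
    "make_allometry_sample",
]


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom.

    ``fabric_axes`` are rows (u1, u2, u3) in world (x, y, z) coordinates;
    ``fabric_eigenvalues`` is a nominal descending positive triple describing
    the expected fabric ordering (not a calibrated magnitude claim).
    """

    fabric_axes: np.ndarray | None = None
    fabric_eigenvalues: np.ndarray | None = None
    bvtv: float | None = None
    tb_sp_mm: float | None = None
    condyle_centers_mm: tuple | None = None
    long_axis: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fabric_axes is not None:
            self.fabric_axes = np.asarray(self.fabric_axes, dtype=float)
            gram = self.fabric_axes @ self.fabric_axes.T
            if not np.allclose(gram, np.eye(3), atol=1e-8):
                raise ValueError("fabric_axes must be orthonormal rows")
        if self.fabric_eigenvalues is not None:
            ev = np.asarray(self.fabric_eigenvalues, dtype=float)
            if np.any(ev <= 0) or np.any(np.diff(ev) > 0):
                raise ValueError("fabric_eigenvalues must be positive and descending")
            self.fabric_eigenvalues = ev


def _unit(v, name="axis") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be non-zero")
    return v / n


def _orthonormal_complement(axis: np.ndarray):
    """Two unit vectors completing ``axis`` to a right-handed basis."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _voxel_centers(shape, spacing):
    """World (x, y, z) coordinates of all voxel centres, origin at 0."""
    ax = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=True)
    return xx, yy, zz


def make_rod_lattice(
    shape_vox,
    spacing_mm,
    axis,
    rod_radius_mm: float,
    pitch_mm: float,
    jitter_frac: float = 0.0,
    seed: int | None = None,
):
    """Parallel cylindrical rods along ``axis`` on a (jittered) square grid.

    Emulates strongly aligned trabecular tracts: the primary fabric
    direction of the result is ``axis`` by construction.
    """
    axis = _unit(axis)
    spacing = _as_triple(spacing_mm, "spacing_mm")
    if not 0 < rod_radius_mm < pitch_mm / 2:
        raise ValueError("require 0 < rod_radius_mm < pitch_mm/2 (rods must not merge)")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape_vox)

    e1, e2 = _orthonormal_complement(axis)
    xx, yy, zz = _voxel_centers(shape, spacing)
    center = (np.asarray(shape[::-1]) - 1) * spacing[::-1] / 2.0
    ux = xx - center[0]
    uy = yy - center[1]
    uz = zz - center[2]
    a1 = ux * e1[0] + uy * e1[1] + uz * e1[2]
    a2 = ux * e2[0] + uy * e2[1] + uz * e2[2]

    # per-rod jitter table indexed by lattice cell
    extent = float(np.max(np.asarray(shape) * spacing))
    n_half = int(np.ceil(extent / pitch_mm)) + 2
    jit = jitter_frac * pitch_mm * rng.uniform(-0.5, 0.5, size=(2 * n_half + 1, 2 * n_half + 1, 2))

    m = np.clip(np.round(a1 / pitch_mm).astype(int), -n_half + 1, n_half - 1)
    n = np.clip(np.round(a2 / pitch_mm).astype(int), -n_half + 1, n_half - 1)
    d2min = np.full(np.broadcast_shapes(a1.shape, a2.shape), np.inf)
    for dm in (-1, 0, 1):
        for dn in (-1, 0, 1):
            mm_ = m + dm
            nn_ = n + dn
            cx = mm_ * pitch_mm + jit[mm_ + n_half, nn_ + n_half, 0]
            cy = nn_ * pitch_mm + jit[mm_ + n_half, nn_ + n_half, 1]
            d2 = (a1 - cx) ** 2 + (a2 - cy) ** 2
            np.minimum(d2min, d2, out=d2min)
    grid = d2min <= rod_radius_mm**2

    vol = BinaryVolume(grid=grid, spacing_mm=spacing)
    truth = PhantomTruth(
        fabric_axes=np.stack([axis, e1, e2]),
        fabric_eigenvalues=np.array([2.0, 1.0, 1.0]),
        bvtv=vol.bone_fraction,
        tb_sp_mm=pitch_mm - 2 * rod_radius_mm,
    )
    return vol, truth


def make_strut_lattice(
    shape_vox,
    spacing_mm,
    rod_radius_mm: float,
    pitch_mm: float,
    jitter_frac: float = 0.0,
    seed: int | None = None,
):
    """Connected trabecular network: union of three orthogonal rod lattices.

    Unlike a single parallel-rod lattice (whose rods never touch), the
    crossing struts form one 26-connected network, which is what the
    floating-voxel cleanup step of the segmentation protocols assumes of
    real cancellous bone.  The fabric is near-isotropic by symmetry.
    """
    ss = np.random.SeedSequence(seed)
    grids = None
    for child, axis in zip(ss.spawn(3), np.eye(3)):
        v, _ = make_rod_lattice(
            shape_vox, spacing_mm, axis, rod_radius_mm, pitch_mm,
            jitter_frac=jitter_frac,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        grids = v.grid if grids is None else grids | v.grid
    vol = BinaryVolume(grid=grids, spacing_mm=_as_triple(spacing_mm, "spacing_mm"))
    truth = PhantomTruth(
        fabric_axes=np.eye(3),
        fabric_eigenvalues=np.array([1.0, 1.0, 1.0]) + np.array([2e-9, 1e-9, 0.0]),
        bvtv=vol.bone_fraction,
        tb_sp_mm=pitch_mm - 2 * rod_radius_mm,
    )
    return vol, truth


def make_plate_stack(shape_vox, spacing_mm, normal, plate_thickness_mm, gap_mm):
    """Parallel solid slabs normal to ``normal`` (plate-like trabeculae).

    The tertiary fabric direction of the result is ``normal``; trabecular
    spacing equals the inter-slab gap by construction.
    """
    if plate_thickness_mm <= 0 or gap_mm <= 0:
        raise ValueError("plate thickness and gap must be > 0")
    normal = _unit(normal, "normal")
    spacing = _as_triple(spacing_mm, "spacing_mm")
    shape = tuple(int(s) for s in shape_vox)

    xx, yy, zz = _voxel_centers(shape, spacing)
    s = xx * normal[0] + yy * normal[1] + zz * normal[2]
    period = plate_thickness_mm + gap_mm
    # centre a plate at mid-volume so thin stacks still contain bone
    mid = float(np.mean(s))
    phase = np.mod(s - mid + plate_thickness_mm / 2.0, period)
    grid = np.broadcast_to(phase < plate_thickness_mm, np.broadcast_shapes(*[a.shape for a in (xx, yy, zz)])).copy()

    e1, e2 = _orthonormal_complement(normal)
    vol = BinaryVolume(grid=grid, spacing_mm=spacing)
    truth = PhantomTruth(
        fabric_axes=np.stack([e1, e2, normal]),
        fabric_eigenvalues=np.array([1.3, 1.3, 0.4]),
        bvtv=plate_thickness_mm / period,
        tb_sp_mm=gap_mm,
    )
    return vol, truth


def make_isotropic_boolean(
    shape_vox,
    spacing_mm,
    grain_radius_mm: float,
    target_bvtv: float,
    seed: int | None = None,
    tolerance: float = 0.02,
):
    """Boolean model: union of uniformly placed spheres hitting a target BV/TV.

    Spheres are added one at a time until the achieved bone fraction is
    within ``tolerance`` (fractional points) of ``target_bvtv``.  The result
    has no principal direction: its fabric is isotropic up to sampling noise.
    """
    if not 0 < target_bvtv < 1:
        raise ValueError("target_bvtv must be in (0, 1)")
    spacing = _as_triple(spacing_mm, "spacing_mm")
    shape = tuple(int(s) for s in shape_vox)
    rng = np.random.default_rng(seed)

    grid = np.zeros(shape, dtype=bool)
    total = grid.size
    extent = np.asarray(shape) * spacing  # (z, y, x)
    r_vox = grain_radius_mm / spacing
    # template sphere in voxel units
    ax = [np.arange(-int(np.ceil(r_vox[a])), int(np.ceil(r_vox[a])) + 1) for a in range(3)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=True)
    tmpl = (
        (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    ) <= grain_radius_mm**2
    if not tmpl.any():
        raise ValueError("grain radius smaller than a voxel")
    half = np.array([len(a) // 2 for a in ax])

    sphere_frac = tmpl.sum() / total
    max_attempts = int(20 * max(1.0, -np.log(max(1e-9, 1 - target_bvtv)) / max(sphere_frac, 1e-12)))
    count = 0
    n_bone = 0
    while True:
        frac = n_bone / total
        if abs(frac - target_bvtv) <= tolerance and frac > 0:
            break
        if frac > target_bvtv + tolerance or count > max_attempts:
            raise ValueError(
                "target bone fraction unreachable with this grain radius "
                f"(reached {frac:.3f} after {count} spheres)"
            )
        c = rng.uniform(0, 1, 3) * extent  # (z, y, x) world
        ci = np.round(c / spacing).astype(int)
        lo = np.maximum(ci - half, 0)
        hi = np.minimum(ci + half + 1, np.asarray(shape))
        tlo = lo - (ci - half)
        thi = tmpl.shape - ((ci + half + 1) - hi)
        sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        t = tmpl[tlo[0]:thi[0], tlo[1]:thi[1], tlo[2]:thi[2]]
        added = np.count_nonzero(t & ~sub)
        sub |= t
        n_bone += added
        count += 1

    vol = BinaryVolume(grid=grid, spacing_mm=spacing)
    truth = PhantomTruth(
        fabric_axes=np.eye(3),
        fabric_eigenvalues=np.array([1.0, 1.0, 1.0]) + np.array([2e-9, 1e-9, 0.0]),
        bvtv=vol.bone_fraction,
        tb_sp_mm=None,
        extras={"n_grains": count, "grain_radius_mm": grain_radius_mm},
    )
    return vol, truth


def corrupt_ct(
    binary: BinaryVolume,
    bone_value: float = 255.0,
    gradient_amplitude: float = 60.0,
    impulse_frac: float = 0.05,
    blur_sigma_vox: float = 0.0,
    seed: int | None = None,
) -> VoxelVolume:
    """Turn a binary phantom into corrupted pseudo-CT.

    The corruption model is the regime the fossil-scan segmentation protocol
    targets: a smooth low-frequency background field (beam-hardening-like
    drift, peak amplitude ``gradient_amplitude``) plus salt-and-pepper
    impulses at ``impulse_frac`` of voxels, with an optional Gaussian blur.
    With all knobs at zero the output is exactly ``bone_value * grid``.
    """
    if not 0 <= impulse_frac < 1:
        raise ValueError("impulse_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = binary.grid.astype(np.float64) * float(bone_value)

    if gradient_amplitude != 0:
        # drift varies across the whole specimen, as beam hardening does,
        # not at trabecular scale: one control interval spans the volume
        coarse = rng.standard_normal((2, 2, 2))
        factors = [s / 2 for s in g.shape]
        fieldv = ndi.zoom(coarse, factors, order=3, mode="nearest", grid_mode=True)
        fieldv *= gradient_amplitude / np.max(np.abs(fieldv))
        g = g + fieldv

    if blur_sigma_vox > 0:
        g = ndi.gaussian_filter(g, blur_sigma_vox, mode="nearest")

    if impulse_frac > 0:
        n_imp = int(round(impulse_frac * g.size))
        flat_idx = rng.choice(g.size, size=n_imp, replace=False)
        salt = rng.random(n_imp) < 0.5
        g.ravel()[flat_idx[salt]] = float(bone_value)
        g.ravel()[flat_idx[~salt]] = 0.0

    return VoxelVolume(
        grid=g,
        spacing_mm=binary.spacing_mm,
        origin_mm=binary.origin_mm,
        value_range=(float(np.min(g)), float(np.max(g))),
    )


def make_bone_phantom(
    length_mm: float = 30.0,
    shaft_radius_mm: float = 4.0,
    condyle_radius_mm: float = 3.5,
    condyle_sep_mm: float = 5.0,
    spacing_mm: float = 0.25,
    fill_spec: dict | None = None,
):
    """A femur-like phantom: cortical shaft tube along +z with two distal
    condylar spheres at known centres, the epiphyseal ends filled with a rod
    lattice per ``fill_spec``.

    ``fill_spec`` keys: ``axis`` (world xyz, default +z), ``rod_radius_mm``,
    ``pitch_mm``, ``jitter_frac``, ``seed``.  The distal end (condyles) is at
    low z, the proximal end at high z; truth records the long axis, both
    condyle centres and the fill fabric.
    """
    if condyle_sep_mm <= 0:
        raise ValueError("condyle_sep_mm must be > 0")
    fill = {"axis": (0.0, 0.0, 1.0), "rod_radius_mm": 0.35, "pitch_mm": 1.4,
            "jitter_frac": 0.0, "seed": 0}
    if fill_spec:
        fill.update(fill_spec)
    axis = _unit(fill["axis"])

    spacing = _as_triple(spacing_mm, "spacing_mm")
    margin = 2.0
    size_x = max(condyle_sep_mm + 2 * condyle_radius_mm, 2 * shaft_radius_mm) + 2 * margin
    size_y = max(2 * condyle_radius_mm, 2 * shaft_radius_mm) + 2 * margin
    size_z = length_mm + 2 * margin
    shape = tuple(int(np.ceil(s / sp)) for s, sp in zip((size_z, size_y, size_x), spacing))

    xx, yy, zz = _voxel_centers(shape, spacing)
    cx, cy = size_x / 2.0, size_y / 2.0
    z0, z1 = margin, margin + length_mm  # distal, proximal shaft ends

    wall = max(3 * float(spacing.min()), 0.8)
    rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
    in_shaft = (rho2 <= shaft_radius_mm**2) & (zz >= z0) & (zz <= z1)
    shaft_shell = in_shaft & (rho2 >= (shaft_radius_mm - wall) ** 2)
    # close the proximal end with a cap so the head region is bounded
    prox_cap = (rho2 <= shaft_radius_mm**2) & (zz >= z1 - wall) & (zz <= z1)

    c_med = np.array([cx - condyle_sep_mm / 2.0, cy, z0])  # medial for a right bone
    c_lat = np.array([cx + condyle_sep_mm / 2.0, cy, z0])
    d_med2 = (xx - c_med[0]) ** 2 + (yy - c_med[1]) ** 2 + (zz - c_med[2]) ** 2
    d_lat2 = (xx - c_lat[0]) ** 2 + (yy - c_lat[1]) ** 2 + (zz - c_lat[2]) ** 2
    cond_solid = (d_med2 <= condyle_radius_mm**2) | (d_lat2 <= condyle_radius_mm**2)
    cond_shell = cond_solid & (
        (d_med2 >= (condyle_radius_mm - wall) ** 2) & (d_lat2 >= (condyle_radius_mm - wall) ** 2)
    )

    # condyles must touch the shaft
    if condyle_sep_mm / 2.0 > condyle_radius_mm + shaft_radius_mm:
        raise ValueError("condyles are geometrically disjoint from the shaft")

    # trabecular fill: rods along `axis` inside the condyles and the proximal head
    rod_r = fill["rod_radius_mm"]
    pitch = fill["pitch_mm"]
    rods, _ = make_rod_lattice(
        shape, spacing, axis, rod_r, pitch,
        jitter_frac=fill["jitter_frac"], seed=fill["seed"],
    )
    head_c = np.array([cx, cy, z1 - shaft_radius_mm])
    d_head2 = (xx - head_c[0]) ** 2 + (yy - head_c[1]) ** 2 + (zz - head_c[2]) ** 2
    fill_region = cond_solid | (d_head2 <= (shaft_radius_mm - 0.5 * wall) ** 2)
    trabecular = rods.grid & np.broadcast_to(fill_region, rods.grid.shape)
    # cancellous region proper: inside the cortical shells (for VOI packing)
    cancellous = (
        (d_med2 <= (condyle_radius_mm - wall) ** 2)
        | (d_lat2 <= (condyle_radius_mm - wall) ** 2)
        | (d_head2 <= (shaft_radius_mm - wall) ** 2)
    )

    grid = shaft_shell | prox_cap | cond_shell | trabecular
    vol = BinaryVolume(grid=grid, spacing_mm=spacing)

    e1, e2 = _orthonormal_complement(axis)
    truth = PhantomTruth(
        fabric_axes=np.stack([axis, e1, e2]),
        fabric_eigenvalues=np.array([2.0, 1.0, 1.0]),
        bvtv=vol.bone_fraction,
        tb_sp_mm=pitch - 2 * rod_r,
        condyle_centers_mm=(c_med, c_lat),
        long_axis=np.array([0.0, 0.0, 1.0]),
        extras={"head_center_mm": head_c, "head_radius_mm": shaft_radius_mm,
                "condyle_radius_mm": condyle_radius_mm, "side": "right",
                "cancellous_mask": np.broadcast_to(cancellous, grid.shape).copy()},
    )
    return vol, truth


def condyle_surface_points(truth: PhantomTruth, n_per_condyle: int = 60,
                           seed: int | None = None):
    """Sample surface-point patches on the two condyle spheres of a phantom.

    Returns (medial_points, lateral_points), each ``(n, 3)`` world xyz, drawn
    from the distal-facing half of each sphere (as a user would digitise)."""
    if truth.condyle_centers_mm is None:
        raise ValueError("phantom truth has no condyle centres")
    rng = np.random.default_rng(seed)
    r = truth.extras.get("condyle_radius_mm")
    out = []
    for c in truth.condyle_centers_mm:
        v = rng.standard_normal((n_per_condyle, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 2] = -np.abs(v[:, 2])  # distal-facing hemisphere
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        out.append(np.asarray(c) + r * v)
    return tuple(out)


def make_score_table(
    n_bones: int,
    n_scorers: int = 5,
    bone_sd: float = 1.0,
    scorer_sd: float = 0.3,
    residual_sd: float = 0.3,
    na_frac: float = 0.0,
    seed: int | None = None,
    scale_max: int = 8,
) -> pd.DataFrame:
    """Two-way rater table: score = bone effect + scorer effect + residual.

    Scores are rounded half-up to integers and clipped to ``[0, scale_max]``;
    missing cells (NaN) are planted at ``na_frac``.  Rows are bones, columns
    scorers."""
    if min(bone_sd, scorer_sd, residual_sd) < 0:
        raise ValueError("standard deviations must be >= 0")
    if not 0 <= na_frac < 1:
        raise ValueError("na_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mu = scale_max / 2.0
    bone = rng.normal(0, bone_sd, size=(n_bones, 1))
    scorer = rng.normal(0, scorer_sd, size=(1, n_scorers))
    resid = rng.normal(0, residual_sd, size=(n_bones, n_scorers))
    raw = mu + bone + scorer + resid
    scores = np.clip(np.floor(raw + 0.5), 0, scale_max)  # half-up rounding
    scores = scores.astype(float)
    if na_frac > 0:
        n_na = int(round(na_frac * scores.size))
        idx = rng.choice(scores.size, size=n_na, replace=False)
        scores.ravel()[idx] = np.nan
    return pd.DataFrame(
        scores,
        index=[f"bone_{i}" for i in range(n_bones)],
        columns=[f"scorer_{j + 1}" for j in range(n_scorers)],
    )


def make_allometry_sample(
    n: int,
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    hetero_power: float = 0.0,
    seed: int | None = None,
    x_range: tuple = (1.0, 10.0),
):
    """Bivariate sample y = intercept + slope*x + eps with sd(eps) ∝ x^p.

    ``hetero_power = 0`` gives homoscedastic Gaussian noise; ``> 0`` gives
    variance growing with x (the pattern a Breusch-Pagan test should flag)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    sd = noise_sd * x**hetero_power
    y = intercept + slope * x + rng.standard_normal(n) * sd
    return x, y
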