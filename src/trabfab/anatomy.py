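"""Anatomically referenced fabric directions for femora.

The bone-fixed frame is right-handed with +x lateral, +y anterior and
+z proximal: z is the principal axis of inertia of the whole bone (sign
resolved by a proximal hint point), y is the normalised cross product of z
with the medial-to-lateral condyle-centre vector, and x = y cross z.  Left
bones are mirrored about their sagittal plane before frame construction so
left and right elements report identical anatomical angles.

Mean regional fabric directions are vectorial means of the per-VOI primary
fabric axes (antipodally normalised: fabric directions are axes, not
vectors), reported as inclination angles and equal-angle (Wulff)
stereographic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .volumes import BinaryVolume

__all__ = [
    "AnatomicalFrame",
    "MeanDirection",
    "StereoPoint",
    "principal_axis",
    "fit_sphere",
    "build_frame",
    "axial_mean",
    "inclination_angles",
    "stereo_project",
    "stereo_unproject",
]


@dataclass
class AnatomicalFrame:
    origin_mm: np.ndarray
    x_axis: np.ndarray  # +lateral
    y_axis: np.ndarray  # +anterior
    z_axis: np.ndarray  # +proximal
    side: str = "right"

    def __post_init__(self):
        for name in ("origin_mm", "x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        R = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9):
            raise ValueError("frame must be right-handed (x cross y = z)")

    def to_frame(self, v_world: np.ndarray) -> np.ndarray:
        """Express a world direction in frame coordinates (x, y, z)."""
        v = np.asarray(v_world, dtype=float)
        return np.stack([self.x_axis, self.y_axis, self.z_axis]) @ v

    def reference_axis(self, v_world: np.ndarray) -> np.ndarray:
        """Express a measured fabric axis in frame coordinates; axes measured
        on a left bone are mirrored about the sagittal plane first, matching
        the mirroring of the geometry at frame construction."""
        v = np.asarray(v_world, dtype=float)
        if self.side == "left":
            v = mirror_x(v)
        return self.to_frame(v)


@dataclass
class MeanDirection:
    axis: np.ndarray  # unit, flipped into the +z hemisphere of its frame
    resultant_length: float  # R-bar in [0, 1]
    n: int

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise ValueError("axis must be a unit vector")
        if not 0.0 <= self.resultant_length <= 1.0 + 1e-12:
            raise ValueError("resultant length must be in [0, 1]")


@dataclass
class StereoPoint:
    x: float
    y: float
    hemisphere: str

    def __post_init__(self):
        if self.x**2 + self.y**2 > 1.0 + 1e-9:
            raise ValueError("stereographic point must lie in the unit disc")


def _unit(v, name="vector"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be non-zero")
    return v / n


def principal_axis(geometry, proximal_hint=None, degeneracy_tol: float = 0.01) -> np.ndarray:
    """Long axis of a bone: the inertia-tensor eigenvector with the smallest
    moment.

    ``geometry`` is a BinaryVolume (uniform-density voxel model), a trimesh
    mesh, or an (n, 3) point cloud.  The sign is oriented toward
    ``proximal_hint`` (a world point known to be proximal) when given.
    Raises when the two smallest moments are within ``degeneracy_tol``
    (relative), i.e. there is no distinct long axis.
    """
    if isinstance(geometry, BinaryVolume):
        idx = np.argwhere(geometry.grid)
        if idx.size == 0:
            raise ValueError("empty geometry")
        pts = geometry.index_to_world(idx.astype(float))
    elif hasattr(geometry, "vertices"):
        pts = np.asarray(geometry.vertices, dtype=float)
    else:
        pts = np.asarray(geometry, dtype=float)
    centroid = pts.mean(axis=0)
    q = pts - centroid
    r2 = np.einsum("ij,ij->i", q, q)
    inertia = np.eye(3) * r2.sum() - q.T @ q
    moments, axes = np.linalg.eigh(inertia)  # ascending
    rel_gap = (moments[1] - moments[0]) / max(moments.mean(), 1e-300)
    if rel_gap < degeneracy_tol:
        raise ValueError(
            "inertia tensor is (near-)degenerate: no distinct long axis; "
            "supply the axis manually"
        )
    axis = axes[:, 0]
    if proximal_hint is not None:
        if axis @ (np.asarray(proximal_hint, float) - centroid) < 0:
            axis = -axis
    elif axis[2] < 0:
        axis = -axis
    return axis


def fit_sphere(points) -> tuple:
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic (linear) fit followed by geometric (Levenberg-Marquardt)
    refinement of sum((|p - c| - r)^2).  Returns ``(center, radius, rms)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 points of shape (n, 3)")
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise ValueError("points are coplanar or otherwise ill-conditioned")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(sol[3] + c0 @ c0))

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    fit = least_squares(resid, x0=np.append(c0, r0), method="lm")
    center, radius = fit.x[:3], float(fit.x[3])
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return center, radius, rms


def mirror_x(v: np.ndarray) -> np.ndarray:
    """Reflect a point or direction about the sagittal (x = 0) plane."""
    out = np.array(v, dtype=float, copy=True)
    out[..., 0] = -out[..., 0]
    return out


def build_frame(long_axis, medial_center, lateral_center, side: str = "right",
                origin=None) -> AnatomicalFrame:
    """Anatomical frame from the inertia axis and two condyle-sphere centres.

    ``z = long_axis`` (+proximal); ``y = normalize(z x c)`` with ``c`` the
    medial-to-lateral condyle vector (+anterior); ``x = y x z`` (+lateral).
    For ``side='left'`` all inputs are mirrored about the sagittal plane
    first, so left and right twins yield identical anatomical angles.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    z = _unit(long_axis, "long_axis")
    med = np.asarray(medial_center, dtype=float)
    lat = np.asarray(lateral_center, dtype=float)
    if side == "left":
        z = mirror_x(z)
        med = mirror_x(med)
        lat = mirror_x(lat)
    c = lat - med
    if np.linalg.norm(c) == 0:
        raise ValueError("condyle centres must be distinct")
    cross = np.cross(z, c)
    if np.linalg.norm(cross) < 1e-12 * np.linalg.norm(c):
        raise ValueError("long axis is parallel to the condyle vector")
    y = cross / np.linalg.norm(cross)
    x = np.cross(y, z)
    origin = 0.5 * (med + lat) if origin is None else np.asarray(origin, float)
    return AnatomicalFrame(origin_mm=origin, x_axis=x, y_axis=y, z_axis=z,
                           side=side)


def axial_mean(vectors, frame: AnatomicalFrame | None = None) -> MeanDirection:
    """Vectorial mean of fabric axes with antipodal normalisation.

    Each axis is sign-flipped into the hemisphere of the running resultant,
    then the result is refined by a second pass aligning all axes to the
    first-pass mean (removing order dependence).  If a frame is given the
    mean is expressed in frame coordinates and flipped into +z (proximal).
    """
    vs = np.asarray(vectors, dtype=float)
    if vs.ndim != 2 or vs.shape[1] != 3 or len(vs) == 0:
        raise ValueError("need an (n, 3) array with n >= 1")
    vs = vs / np.linalg.norm(vs, axis=1, keepdims=True)

    resultant = vs[0].copy()
    for v in vs[1:]:
        resultant += v if v @ resultant >= 0 else -v
    for _ in range(2):  # align-to-mean refinement
        norm = np.linalg.norm(resultant)
        if norm < 1e-12:
            raise ValueError("degenerate axis set: zero resultant")
        mean = resultant / norm
        signs = np.where(vs @ mean >= 0, 1.0, -1.0)
        resultant = (vs * signs[:, None]).sum(axis=0)
    norm = np.linalg.norm(resultant)
    if norm < 1e-12:
        raise ValueError("degenerate axis set: zero resultant")
    axis = resultant / norm
    if frame is not None:
        axis = frame.reference_axis(axis)
    if axis[2] < 0:
        axis = -axis
    return MeanDirection(axis=axis, resultant_length=float(norm / len(vs)), n=len(vs))


def inclination_angles(direction, frame: AnatomicalFrame | None = None,
                       tol: float = 1e-9) -> tuple:
    """(anterior, medial) inclination of an axis, in degrees.

    Anterior inclination is the signed angle between +z (proximal) and the
    projection of the axis onto the sagittal (y-z) plane, anterior positive;
    medial inclination is the analogue in the coronal (x-z) plane, medial
    (-x) positive.  The axis is given in frame coordinates, or in world
    coordinates together with ``frame``.
    """
    a = direction.axis if isinstance(direction, MeanDirection) else np.asarray(direction, float)
    if frame is not None:
        a = frame.to_frame(a)
    a = _unit(a, "axis")
    if a[2] < 0:
        a = -a
    if abs(a[1]) < tol and abs(a[2]) < tol:
        raise ValueError("axis lies in the transverse plane: sagittal angle undefined")
    if abs(a[0]) < tol and abs(a[2]) < tol:
        raise ValueError("axis lies in the transverse plane: coronal angle undefined")
    anterior = np.degrees(np.arctan2(a[1], a[2]))
    medial = np.degrees(np.arctan2(-a[0], a[2]))
    return float(anterior), float(medial)


def stereo_project(axis, hemisphere: str = "north") -> StereoPoint:
    """Equal-angle (Wulff) stereographic projection of an axis.

    The axis is first flipped into the chosen hemisphere; the plot radius is
    ``tan(theta / 2)`` with theta the angle from the hemisphere's pole, and
    the azimuth (from +x toward +y) is preserved.
    """
    if hemisphere not in ("north", "south"):
        raise ValueError("hemisphere must be 'north' or 'south'")
    a = _unit(axis)
    pole_z = 1.0 if hemisphere == "north" else -1.0
    if a[2] * pole_z < 0:
        a = -a
    cos_t = np.clip(a[2] * pole_z, -1.0, 1.0)
    theta = np.arccos(cos_t)
    r = np.tan(theta / 2.0)
    s = np.hypot(a[0], a[1])
    if s < 1e-15:
        return StereoPoint(0.0, 0.0, hemisphere)
    return StereoPoint(float(r * a[0] / s), float(r * a[1] / s), hemisphere)


def stereo_unproject(point: StereoPoint) -> np.ndarray:
    """Inverse Wulff projection back to a unit axis in the point's hemisphere."""
    r = np.hypot(point.x, point.y)
    theta = 2.0 * np.arctan(r)
    pole_z = 1.0 if point.hemisphere == "north" else -1.0
    if r < 1e-15:
        return np.array([0.0, 0.0, pole_z])
    s = np.sin(theta)
    return np.array([s * point.x / r, s * point.y / r, pole_z * np.cos(theta)])
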