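"""Anatomical frame, sphere fitting, axial means, angles, stereoplots."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from trabfab import anatomy, phantoms
from trabfab.volumes import BinaryVolume


def capsule_mask(axis=None, n=48, spacing=0.25):
    """Capsule-ish elongated blob for inertia-axis tests."""
    ax = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    idx = np.indices((n, n, n)).reshape(3, -1).T
    xyz = idx[:, ::-1] * spacing
    c = (n - 1) * spacing / 2.0
    u = xyz - c
    t = u @ ax
    radial = np.linalg.norm(u - np.outer(t, ax), axis=1)
    mask = (np.abs(t) < 4.5) & (radial < 1.2)
    return BinaryVolume(grid=mask.reshape(n, n, n), spacing_mm=spacing)


class TestPrincipalAxis:
    def test_capsule_long_axis(self):
        ax = anatomy.principal_axis(capsule_mask(), proximal_hint=(6, 6, 100))
        assert np.degrees(np.arccos(abs(ax[2]))) < 2.0
        assert ax[2] > 0  # oriented toward the hint

    def test_rotated_capsule_rotates_axis(self):
        R = Rotation.from_euler("xy", [35, 20], degrees=True).as_matrix()
        target = R @ np.array([0, 0, 1.0])
        ax = anatomy.principal_axis(capsule_mask(axis=target))
        assert np.degrees(np.arccos(min(1, abs(ax @ target)))) < 2.0

    def test_sphere_is_degenerate(self):
        n = 32
        idx = np.indices((n, n, n)).reshape(3, -1).T
        c = (n - 1) / 2.0
        mask = (np.linalg.norm(idx - c, axis=1) < 12).reshape(n, n, n)
        with pytest.raises(ValueError, match="degenerate"):
            anatomy.principal_axis(BinaryVolume(grid=mask, spacing_mm=0.25))


class TestFitSphere:
    def test_exact_points_recovered(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((20, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        c, r, rms = anatomy.fit_sphere(np.array([1.0, 2.0, 3.0]) + 5.0 * v)
        np.testing.assert_allclose(c, [1, 2, 3], atol=1e-9)
        assert r == pytest.approx(5.0, abs=1e-9)
        assert rms < 1e-9

    def test_noisy_points_center_error_bounded(self):
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(50):
            v = rng.standard_normal((20, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = 5.0 * v + rng.normal(0, 0.05, (20, 3))
            c, r, _ = anatomy.fit_sphere(pts)
            errs.append(np.linalg.norm(c))
        # sd/sqrt(n/3)-scale bound on the centre estimate, with slack
        assert np.mean(errs) < 3.0 * 0.05 * np.sqrt(3.0 / 20.0)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="coplanar|ill-conditioned"):
            anatomy.fit_sphere(pts)


class TestBuildFrame:
    def test_canonical_right_femur(self):
        fr = anatomy.build_frame((0, 0, 1), (-5, 0, 0), (5, 0, 0), side="right")
        np.testing.assert_allclose(fr.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.z_axis, [0, 0, 1], atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_frame_always_orthonormal_right_handed(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(3)
        z /= np.linalg.norm(z)
        med = rng.standard_normal(3) * 5
        lat = med + rng.standard_normal(3) * 5
        if np.linalg.norm(np.cross(z, lat - med)) < 1e-6:
            return
        fr = anatomy.build_frame(z, med, lat, side="right")
        R = np.stack([fr.x_axis, fr.y_axis, fr.z_axis])
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(np.cross(fr.x_axis, fr.y_axis), fr.z_axis,
                                   atol=1e-12)

    def test_rotation_equivariance(self):
        R = Rotation.from_euler("zyx", [30, 40, 10], degrees=True).as_matrix()
        z = np.array([0.1, -0.2, 0.97])
        z /= np.linalg.norm(z)
        med, lat = np.array([-4.0, 1.0, 0.5]), np.array([4.0, -0.5, 0.2])
        a = anatomy.build_frame(z, med, lat)
        b = anatomy.build_frame(R @ z, R @ med, R @ lat)
        for ax in ("x_axis", "y_axis", "z_axis"):
            np.testing.assert_allclose(getattr(b, ax), R @ getattr(a, ax),
                                       atol=1e-10)

    def test_left_right_mirror_twins_agree(self):
        """A left-side element (geometry mirrored about the sagittal plane)
        must yield the same anatomical angles as its right-side twin."""
        z = np.array([0.05, 0.1, 0.99])
        z /= np.linalg.norm(z)
        med, lat = np.array([-4.0, 0.3, 0.1]), np.array([4.0, -0.2, 0.4])
        u1 = np.array([0.1, 0.35, 0.93])
        u1 /= np.linalg.norm(u1)
        fr_r = anatomy.build_frame(z, med, lat, side="right")
        ang_r = anatomy.inclination_angles(anatomy.axial_mean([u1], frame=fr_r))
        # mirrored twin: x-coordinates negated; medial/lateral labels preserved
        fr_l = anatomy.build_frame(anatomy.mirror_x(z), anatomy.mirror_x(med),
                                   anatomy.mirror_x(lat), side="left")
        ang_l = anatomy.inclination_angles(
            anatomy.axial_mean([anatomy.mirror_x(u1)], frame=fr_l))
        np.testing.assert_allclose(ang_l, ang_r, atol=1e-12)

    def test_parallel_axis_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            anatomy.build_frame((1, 0, 0), (-5, 0, 0), (5, 0, 0))


class TestAxialMean:
    def test_antipodal_pair_identity(self):
        md = anatomy.axial_mean(np.array([[0, 0, 1.0], [0, 0, -1.0]]))
        np.testing.assert_allclose(md.axis, [0, 0, 1])
        assert md.resultant_length == pytest.approx(1.0)

    def test_symmetric_pair_closed_form(self):
        t = np.radians(10)
        vs = np.array([[np.sin(t), 0, np.cos(t)], [-np.sin(t), 0, np.cos(t)]])
        md = anatomy.axial_mean(vs)
        np.testing.assert_allclose(md.axis, [0, 0, 1], atol=1e-12)
        assert md.resultant_length == pytest.approx(np.cos(t), abs=1e-12)

    def test_concentrated_axial_sample_recovers_pole(self):
        rng = np.random.default_rng(2)
        # Watson-type concentrated axial sample about +z
        v = rng.normal([0, 0, 1], 0.08, (100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], 100)
        md = anatomy.axial_mean(v * signs[:, None])
        assert np.degrees(np.arccos(abs(md.axis[2]))) < 3.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_input_sign_flips(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal([0, 0, 1], 0.3, (12, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], 12)
        a = anatomy.axial_mean(v)
        b = anatomy.axial_mean(v * signs[:, None])
        np.testing.assert_allclose(np.abs(a.axis @ b.axis), 1.0, atol=1e-9)
        assert a.resultant_length == pytest.approx(b.resultant_length, abs=1e-9)

    def test_degenerate_balanced_set_rejected(self):
        vs = np.array([[1.0, 0, 0], [0, 1.0, 0]])  # resultant refinement breaks
        md = anatomy.axial_mean(vs)  # 45-degree mean is fine
        assert md.resultant_length > 0


class TestInclinationAngles:
    def test_pole_is_zero_zero(self):
        assert anatomy.inclination_angles(np.array([0, 0, 1.0])) == (0.0, 0.0)

    def test_pure_anterior_tilt_closed_form(self):
        t = np.radians(20)
        ant, med = anatomy.inclination_angles(np.array([0, np.sin(t), np.cos(t)]))
        assert ant == pytest.approx(20.0, abs=1e-9)
        assert med == pytest.approx(0.0, abs=1e-9)

    def test_mixed_axis_closed_form_inverse(self):
        # construct an axis with known projection angles: anterior 10 deg,
        # medial -7 deg (i.e. 7 deg lateral), then recover both
        v = np.array([np.tan(np.radians(7)), np.tan(np.radians(10)), 1.0])
        v /= np.linalg.norm(v)
        ant, med = anatomy.inclination_angles(v)
        assert ant == pytest.approx(10.0, abs=1e-9)
        assert med == pytest.approx(-7.0, abs=1e-9)

    def test_transverse_axis_undefined(self):
        with pytest.raises(ValueError, match="undefined|transverse"):
            anatomy.inclination_angles(np.array([1.0, 0, 0]))


class TestStereoProjection:
    @pytest.mark.parametrize("axis,expected", [
        ((0, 0, 1.0), (0.0, 0.0)),
        ((1.0, 0, 0), (1.0, 0.0)),           # 90 deg from pole: tan(45)=1
        ((0, np.sin(np.radians(45)), np.cos(np.radians(45))),
         (0.0, np.tan(np.radians(22.5)))),
    ])
    def test_wulff_radii(self, axis, expected):
        p = anatomy.stereo_project(np.asarray(axis), "north")
        assert (p.x, p.y) == pytest.approx(expected, abs=1e-9)

    def test_southern_hemisphere_flip(self):
        p = anatomy.stereo_project(np.array([0, 0, 1.0]), "south")
        assert (p.x, p.y) == (0.0, 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_projection_round_trips(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n < 1e-6:
            return
        v /= n
        for hemi in ("north", "south"):
            p = anatomy.stereo_project(v, hemi)
            back = anatomy.stereo_unproject(p)
            np.testing.assert_allclose(abs(back @ v), 1.0, atol=1e-12)
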