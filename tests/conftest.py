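"""Shared fixtures: small phantoms generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

from trabfab import phantoms
from trabfab.volumes import SphereVOI

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def center_voi(vol, radius_mm):
    c = (np.asarray(vol.shape[::-1], float) - 1) * vol.spacing_xyz / 2.0
    return SphereVOI(center_mm=c, radius_mm=radius_mm)


@pytest.fixture(scope="session")
def rod_volume():
    """Axis-aligned rod lattice, 60^3 voxels at 0.05 mm (extent a multiple of
    the 1 mm pitch, so the analytic bone fraction applies)."""
    vol, truth = phantoms.make_rod_lattice(
        (60, 60, 60), 0.05, (0, 0, 1), rod_radius_mm=0.2, pitch_mm=1.0,
        jitter_frac=0.0, seed=11)
    return vol, truth


@pytest.fixture(scope="session")
def plate_volume():
    vol, truth = phantoms.make_plate_stack(
        (80, 80, 80), 0.05, (0, 0, 1), plate_thickness_mm=0.2, gap_mm=0.8)
    return vol, truth


@pytest.fixture(scope="session")
def strut_volume():
    """Connected 3D strut network at 64^3 (the clean segmentation target)."""
    vol, truth = phantoms.make_strut_lattice(
        (64, 64, 64), 0.05, rod_radius_mm=0.2, pitch_mm=1.0, seed=21)
    return vol, truth


@pytest.fixture(scope="session")
def iso_volume():
    vol, truth = phantoms.make_isotropic_boolean(
        (72, 72, 72), 0.06, grain_radius_mm=0.15, target_bvtv=0.3, seed=31)
    return vol, truth
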