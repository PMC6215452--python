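"""Staged whole-bone analysis pipeline with provenance and cached stages.

``run_pipeline`` executes simulate -> segment -> pack-vois -> fabric ->
frame -> refdir (-> stats) on a synthetic bone phantom, writing every
intermediate artefact (TIFF stacks, CSV tables, YAML sidecars) into one
output directory.  A stage whose outputs already exist is skipped, so
deleting an intermediate regenerates only that stage and everything
downstream.  A provenance record (config hash, seeds, package and library
versions) makes any artefact reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, anatomy, fabric, io, phantoms, segmentation, stats, voi
from .volumes import BinaryVolume

log = logging.getLogger("trabfab.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.  Every stochastic stage derives its
    seed deterministically from ``seed``."""

    out_dir: str = "trabfab_run"
    seed: int = 0
    # phantom
    length_mm: float = 30.0
    shaft_radius_mm: float = 4.5
    condyle_radius_mm: float = 4.0
    condyle_sep_mm: float = 5.0
    spacing_mm: float = 0.2
    tilt_anterior_deg: float = 20.0
    rod_radius_mm: float = 0.6
    rod_pitch_mm: float = 1.6
    side: str = "right"
    # corruption (the noise regime protocol 4 targets)
    bone_value: float = 255.0
    gradient_amplitude: float = 60.0
    impulse_frac: float = 0.05
    # segmentation
    protocol: int = 4
    window_radius_px: int = 5
    contrast_threshold: float = 30.0
    median3d_radius_px: int = 2
    background_median_radius_px: int = 8
    mean3d_radius_px: int = 2
    global_threshold: float | None = None
    # VOI packing
    voi_radius_mm: float = 1.3
    containment: float = 0.95
    # fabric
    method: str = "svd"
    n_directions: int = 2049
    n_points: int = 4000
    # stats demo sample
    stats_n: int = 0
    stats_slope: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name, outputs, func, force=False):
    """Run ``func`` unless all of its output paths already exist."""
    outputs = [Path(p) for p in outputs]
    if not force and outputs and all(p.exists() for p in outputs):
        log.info("stage %-10s cached", name)
        return False
    t0 = time.time()
    try:
        func()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    log.info("stage %-10s done in %.1fs", name, time.time() - t0)
    return True


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {k: int(s.generate_state(1)[0] % (2**31)) for k, s in
             zip(("fill", "corrupt", "condyles", "fabric", "stats"), ss.spawn(5))}

    phantom_tif = out / "phantom.tif"
    ct_tif = out / "ct.tif"
    mask_tif = out / "cancellous_mask.tif"
    truth_yaml = out / "truth.yaml"
    cond_csv = [out / "condyle_medial.csv", out / "condyle_lateral.csv"]

    def simulate():
        tilt = np.radians(config.tilt_anterior_deg)
        axis = np.array([0.0, np.sin(tilt), np.cos(tilt)])
        vol, truth = phantoms.make_bone_phantom(
            length_mm=config.length_mm, shaft_radius_mm=config.shaft_radius_mm,
            condyle_radius_mm=config.condyle_radius_mm,
            condyle_sep_mm=config.condyle_sep_mm, spacing_mm=config.spacing_mm,
            fill_spec={"axis": axis, "rod_radius_mm": config.rod_radius_mm,
                       "pitch_mm": config.rod_pitch_mm, "seed": seeds["fill"]},
        )
        io.write_stack(vol, phantom_tif)
        io.write_stack(phantoms.corrupt_ct(
            vol, config.bone_value, config.gradient_amplitude,
            config.impulse_frac, seed=seeds["corrupt"]), ct_tif)
        io.write_stack(BinaryVolume(grid=truth.extras["cancellous_mask"],
                                    spacing_mm=vol.spacing_mm), mask_tif)
        med, lat = phantoms.condyle_surface_points(truth, seed=seeds["condyles"])
        for path, pts in zip(cond_csv, (med, lat)):
            pd.DataFrame(pts, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)
        truth_yaml.write_text(yaml.safe_dump({
            "tilt_anterior_deg": config.tilt_anterior_deg,
            "tb_sp_mm": float(truth.tb_sp_mm),
            "long_axis": [0.0, 0.0, 1.0],
            "side": config.side,
        }))

    seg_tif = out / "segmented.tif"

    def segment():
        ct = io.read_stack(ct_tif)
        mask = io.read_stack(mask_tif, as_binary=True)
        spec = segmentation.ProtocolSpec(
            protocol=config.protocol, window_radius_px=config.window_radius_px,
            contrast_threshold=config.contrast_threshold,
            median3d_radius_px=config.median3d_radius_px,
            background_median_radius_px=config.background_median_radius_px,
            mean3d_radius_px=config.mean3d_radius_px,
            global_threshold=config.global_threshold,
        )
        io.write_stack(segmentation.run_protocol(ct, spec, mask=None), seg_tif)

    vois_csv = out / "vois.csv"

    def pack():
        mask = io.read_stack(mask_tif, as_binary=True)
        vs = voi.ccp_pack(mask, config.voi_radius_mm, containment=config.containment)
        rows = [{"voi_id": i, "cx_mm": v.center_mm[0], "cy_mm": v.center_mm[1],
                 "cz_mm": v.center_mm[2], "radius_mm": v.radius_mm,
                 "containment_frac": float(vs.containment_frac[i])}
                for i, v in enumerate(vs.vois)]
        pd.DataFrame(rows).to_csv(vois_csv, index=False)

    fabric_csv = out / "fabric.csv"

    def run_fabric():
        segv = io.read_stack(seg_tif, as_binary=True)
        tab = pd.read_csv(vois_csv)
        vs = voi.VOISet(
            vois=[voi.SphereVOI((r.cx_mm, r.cy_mm, r.cz_mm), r.radius_mm)
                  for r in tab.itertuples()],
            radius_mm=config.voi_radius_mm)
        params = fabric.FabricParams(method=config.method,
                                     n_directions=config.n_directions,
                                     n_points=config.n_points,
                                     seed=seeds["fabric"])
        fabric.batch_fabric(segv, vs, params).to_csv(fabric_csv, index=False)

    frame_yaml = out / "frame.yaml"

    def build_frame():
        bone = io.read_stack(phantom_tif, as_binary=True)
        hint = bone.index_to_world(np.array(bone.shape, float) * [0.95, 0.5, 0.5])
        lax = anatomy.principal_axis(bone, proximal_hint=hint)
        med = pd.read_csv(cond_csv[0]).to_numpy()
        lat = pd.read_csv(cond_csv[1]).to_numpy()
        cm, rm, _ = anatomy.fit_sphere(med)
        cl, rl, _ = anatomy.fit_sphere(lat)
        fr = anatomy.build_frame(lax, cm, cl, side=config.side)
        frame_yaml.write_text(yaml.safe_dump({
            "origin_mm": fr.origin_mm.tolist(), "x_axis": fr.x_axis.tolist(),
            "y_axis": fr.y_axis.tolist(), "z_axis": fr.z_axis.tolist(),
            "condyle_radii_mm": [float(rm), float(rl)], "side": config.side,
        }))

    angles_csv = out / "angles.csv"

    def refdir():
        fd = yaml.safe_load(frame_yaml.read_text())
        fr = anatomy.AnatomicalFrame(origin_mm=fd["origin_mm"], x_axis=fd["x_axis"],
                                     y_axis=fd["y_axis"], z_axis=fd["z_axis"],
                                 side=fd.get("side", "right"))
        tab = pd.read_csv(fabric_csv)
        ok = tab[tab.ok]
        u1 = ok[["u1x", "u1y", "u1z"]].to_numpy()
        md = anatomy.axial_mean(u1, frame=fr)
        ant, med = anatomy.inclination_angles(md)
        sp = anatomy.stereo_project(md.axis, hemisphere="north")
        pd.DataFrame([{
            "n_vois": md.n, "resultant_length": md.resultant_length,
            "mean_x": md.axis[0], "mean_y": md.axis[1], "mean_z": md.axis[2],
            "anterior_inclination_deg": ant, "medial_inclination_deg": med,
            "stereo_x": sp.x, "stereo_y": sp.y, "hemisphere": sp.hemisphere,
        }]).to_csv(angles_csv, index=False)

    stats_csv = out / "stats.csv"

    def run_stats():
        x, y = phantoms.make_allometry_sample(
            config.stats_n, config.stats_slope, 0.0, noise_sd=0.5,
            seed=seeds["stats"])
        res = stats.perm_test_slope(x, y, n_perm=2000, seed=seeds["stats"])
        lm, p_bp = stats.breusch_pagan(x, y)
        pd.DataFrame([{
            "slope": res.slope, "intercept": res.intercept,
            "r_squared": res.r_squared, "p_perm": res.p_perm,
            "bp_lm": lm, "bp_p": p_bp, "n": res.n,
        }]).to_csv(stats_csv, index=False)

    _stage("simulate", [phantom_tif, ct_tif, mask_tif, truth_yaml, *cond_csv],
           simulate, force)
    _stage("segment", [seg_tif], segment, force)
    _stage("pack-vois", [vois_csv], pack, force)
    _stage("fabric", [fabric_csv], run_fabric, force)
    _stage("frame", [frame_yaml], build_frame, force)
    _stage("refdir", [angles_csv], refdir, force)
    if config.stats_n >= 5:
        _stage("stats", [stats_csv], run_stats, force)

    versions = {"trabfab": __version__, "numpy": np.__version__}
    (out / "provenance.yaml").write_text(yaml.safe_dump({
        "config": asdict(config), "config_hash": config.config_hash(),
        "stage_seeds": seeds, "versions": versions,
    }))
    return out
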