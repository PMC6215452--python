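"""Reading and writing image stacks, tables and sidecar metadata.

Multi-page TIFF stacks carry no spacing metadata of their own, so each TIFF
is paired with a YAML sidecar (``<stem>.meta.yaml``) recording spacing,
origin, kind (binary/greyscale) and any phantom ground-truth parameters.
MetaImage (.mha) files carry spacing and origin natively and are handled
through SimpleITK.  Tables (VOI sets, fabric results, score tables,
allometry samples) are plain CSV; missing scores are the literal string NA.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .volumes import BinaryVolume, VoxelVolume

__all__ = ["read_stack", "write_stack", "read_score_table", "write_score_table"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_stack(vol: VoxelVolume, path) -> Path:
    """Write a volume as multi-page TIFF (+ sidecar) or MetaImage.

    Binary volumes are stored as uint8 0/255; greyscale is stored as uint16
    when integral and in range, otherwise float32.
    """
    path = Path(path)
    is_binary = isinstance(vol, BinaryVolume)
    if is_binary:
        data = vol.grid.astype(np.uint8) * 255
    else:
        g = np.asarray(vol.grid)
        if np.issubdtype(g.dtype, np.integer) and g.min() >= 0 and g.max() <= 65535:
            data = g.astype(np.uint16)
        elif np.allclose(g, np.round(g)) and g.min() >= 0 and g.max() <= 65535:
            data = np.round(g).astype(np.uint16)
        else:
            data = g.astype(np.float32)

    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
        meta = {
            "spacing_mm": [float(s) for s in vol.spacing_mm],
            "origin_mm": [float(o) for o in vol.origin_mm],
            "kind": "binary" if is_binary else "greyscale",
        }
        if vol.value_range is not None:
            meta["value_range"] = [float(v) for v in vol.value_range]
        _sidecar(path).write_text(yaml.safe_dump(meta))
    elif path.suffix.lower() == ".mha":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(float(s) for s in vol.spacing_mm[::-1]))
        img.SetOrigin(tuple(float(o) for o in vol.origin_mm[::-1]))
        img.SetMetaData("kind", "binary" if is_binary else "greyscale")
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    return path


def read_stack(path, as_binary: bool | None = None) -> VoxelVolume:
    """Read a TIFF (+ sidecar) or MetaImage stack.

    A TIFF without its sidecar gets 1 mm spacing with a warning.  Binary
    volumes (sidecar kind, MetaImage tag, or ``as_binary=True``) come back
    as :class:`BinaryVolume` with bone = nonzero.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        spacing = np.ones(3)
        origin = np.zeros(3)
        kind = None
        sc = _sidecar(path)
        if sc.exists():
            meta = yaml.safe_load(sc.read_text())
            spacing = np.asarray(meta.get("spacing_mm", [1, 1, 1]), float)
            origin = np.asarray(meta.get("origin_mm", [0, 0, 0]), float)
            kind = meta.get("kind")
        else:
            warnings.warn(f"no sidecar for {path.name}; assuming 1 mm voxels",
                          stacklevel=2)
    elif path.suffix.lower() == ".mha":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        spacing = np.asarray(img.GetSpacing(), float)[::-1]
        origin = np.asarray(img.GetOrigin(), float)[::-1]
        kind = img.GetMetaData("kind") if img.HasMetaDataKey("kind") else None
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")

    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {data.shape}")
    binary = as_binary if as_binary is not None else kind == "binary"
    if binary:
        return BinaryVolume(grid=data > 0, spacing_mm=spacing, origin_mm=origin)
    return VoxelVolume(grid=data, spacing_mm=spacing, origin_mm=origin)


def write_score_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, na_rep="NA")
    return path


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=["NA"])
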