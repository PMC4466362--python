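"""File formats: TIFF stacks with voxel metadata, CSV object tables, YAML
configs, and machine-readable provenance records."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import VoxelGrid


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a single-channel stack as a multi-page TIFF with spacing/channel
    metadata embedded in the image description."""
    data = grid.data
    if np.issubdtype(data.dtype, np.floating) and np.allclose(data, np.round(data)):
        if data.max() <= np.iinfo(np.uint16).max:
            data = data.astype(np.uint16)
    tifffile.imwrite(
        Path(path),
        data,
        photometric="minisblack",
        metadata={"spacing_nm": list(grid.spacing_nm), "channel": grid.channel},
    )


def read_stack(path: str | Path, spacing_nm: tuple[float, float, float] | None = None,
               channel: str | None = None) -> VoxelGrid:
    """Read a stack written by :func:`write_stack` (or any TIFF, if the voxel
    spacing is supplied explicitly).

    Raises when no voxel-size metadata is found and none is given: intensities
    without physical spacing cannot enter the pipeline.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if spacing_nm is None:
        if "spacing_nm" not in meta:
            raise ValueError(
                f"{path} carries no voxel-size metadata; pass spacing_nm from an "
                "acquisition descriptor"
            )
        spacing_nm = tuple(meta["spacing_nm"])
    if channel is None:
        channel = meta.get("channel", "unknown")
    return VoxelGrid(data=np.asarray(data, dtype=np.float64), spacing_nm=spacing_nm,
                     channel=channel)


def write_objects(df: pd.DataFrame, path: str | Path) -> None:
    """Object table to CSV; floats round-trip exactly (shortest-repr format)."""
    df.to_csv(Path(path), index=False)


def read_objects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration dict."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance_record(cfg: dict, seed: int) -> dict:
    """Machine-readable provenance: config hash, seed, library versions."""
    import scipy
    import skimage

    from . import __version__

    return {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "versions": {
            "npquant": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "tifffile": tifffile.__version__,
            "pandas": pd.__version__,
        },
    }
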