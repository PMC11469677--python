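"""Volume and table I/O with canonical axis handling.

Volumes travel as TIFF (with a small JSON sidecar holding the geometry:
voxel size, bregma voxel, midline and the file's axis order) or as HDF5
(geometry in attributes).  Readers reorder any declared axis permutation to
the canonical (AP, DV, ML) layout, so no other module ever sees a permuted
grid.  Write→read round trips are lossless for integer volumes and exact
to float precision otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .atlas import AXIS_NAMES

__all__ = ["read_volume", "write_volume", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _axis_permutation(axis_order: str) -> tuple[int, ...]:
    names = [a.strip() for a in axis_order.split(",")]
    if sorted(names) != sorted(AXIS_NAMES):
        raise ValueError(f"axis_order must be a permutation of {AXIS_NAMES}, got {axis_order!r}")
    return tuple(names.index(a) for a in AXIS_NAMES)


def write_volume(
    volume: np.ndarray,
    path: str | Path,
    geometry: dict,
) -> None:
    """Write a canonical-order volume as TIFF + JSON sidecar or HDF5.

    ``geometry`` must carry ``voxel_size_um``; bregma/midline entries are
    passed through.  The written axis order is always canonical.
    """
    path = Path(path)
    if "voxel_size_um" not in geometry:
        raise ValueError("geometry must include voxel_size_um")
    meta = {**geometry, "axis_order": ",".join(AXIS_NAMES)}
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(volume), photometric="minisblack")
        sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=np.asarray(volume), compression="gzip")
            for k, v in meta.items():
                ds.attrs[k] = json.dumps(v) if isinstance(v, (list, tuple, dict)) else v
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r} (use .tif/.tiff/.h5/.hdf5)")


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a volume and its geometry, reordering to canonical axes."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        grid = tifffile.imread(path)
        sc = sidecar_path(path)
        if not sc.exists():
            raise ValueError(
                f"TIFF volume {path.name} has no geometry sidecar {sc.name}; "
                "a JSON sidecar with at least voxel_size_um and axis_order is required"
            )
        meta = json.loads(sc.read_text())
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["volume"]
            grid = ds[()]
            meta = {}
            for k, v in ds.attrs.items():
                if isinstance(v, str) and v[:1] in "[{":
                    meta[k] = json.loads(v)
                else:
                    meta[k] = v.item() if hasattr(v, "item") else v
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    if "voxel_size_um" not in meta:
        raise ValueError(f"geometry for {path.name} lacks voxel_size_um")
    order = meta.get("axis_order", ",".join(AXIS_NAMES))
    perm = _axis_permutation(str(order))
    if perm != (0, 1, 2):
        grid = np.transpose(grid, perm)
    meta["axis_order"] = ",".join(AXIS_NAMES)
    return grid, meta
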