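"""Atlas-space density mapping: coordinate transforms, binning, normalization.

Curated skeleton coordinates (native resolution, ~5 µm voxels) are carried
into the 25 µm reference atlas by a registration transform computed
elsewhere; this module only *applies* transforms.  Each native
axon-containing voxel contributes exactly one count to exactly one atlas
voxel (no interpolated splatting), so the atlas-space counts volume retains
the number of native axon voxels exactly — the conservation invariant
``grid total + out_of_bounds = input coordinate count`` is checked on every
pipeline run.  Dividing by the number of labeled neurons at the injection
site yields axon density per cell per atlas voxel, the unit every
downstream analysis consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import AP, DV, ML, AXIS_NAMES, AnnotationVolume, StructureGraph

__all__ = [
    "Affine",
    "DisplacementField",
    "TransformChain",
    "CountsVolume",
    "DensityMap",
    "InjectionQC",
    "transform_coords",
    "bin_to_atlas",
    "normalize_per_cell",
    "injection_qc",
    "group_average",
    "sum_projection",
]


@dataclass(frozen=True)
class Affine:
    """4x4 affine acting on homogeneous (AP, DV, ML, 1) µm coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("affine linear part must be invertible")
        object.__setattr__(self, "matrix", m)

    def apply(self, points_um: np.ndarray) -> tuple[np.ndarray, int]:
        p = np.asarray(points_um, dtype=float)
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out, 0

    def inverse(self) -> "Affine":
        return Affine(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, offset_um: Sequence[float]) -> "Affine":
        m = np.eye(4)
        m[:3, 3] = offset_um
        return cls(m)

    @classmethod
    def scale(cls, factors: Sequence[float]) -> "Affine":
        m = np.eye(4)
        m[0, 0], m[1, 1], m[2, 2] = factors
        return cls(m)


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel additive offset field (µm) on its own regular grid.

    ``offsets`` has shape (3, nAP, nDV, nML); a point at µm position ``x``
    is mapped to ``x + offsets[:, x / grid_voxel_um]`` with trilinear
    interpolation.  Points outside the grid's support take the nearest-edge
    displacement and are tallied.
    """

    offsets: np.ndarray
    grid_voxel_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        o = np.asarray(self.offsets, dtype=float)
        if o.ndim != 4 or o.shape[0] != 3:
            raise ValueError("offsets must have shape (3, nAP, nDV, nML)")
        if self.grid_voxel_um <= 0:
            raise ValueError("grid_voxel_um must be positive")
        object.__setattr__(self, "offsets", o)

    def apply(self, points_um: np.ndarray) -> tuple[np.ndarray, int]:
        p = np.asarray(points_um, dtype=float)
        grid_coords = (p - np.asarray(self.origin_um)) / self.grid_voxel_um
        shape = np.asarray(self.offsets.shape[1:])
        outside = int(np.sum(np.any((grid_coords < 0) | (grid_coords > shape - 1), axis=1)))
        disp = np.stack(
            [
                ndimage.map_coordinates(self.offsets[i], grid_coords.T, order=1, mode="nearest")
                for i in range(3)
            ],
            axis=1,
        )
        return p + disp, outside


@dataclass
class TransformChain:
    """Ordered native → atlas transform composition (affines and/or fields)."""

    transforms: list

    def apply(self, points_um: np.ndarray) -> tuple[np.ndarray, int]:
        p = np.asarray(points_um, dtype=float)
        n_outside = 0
        for t in self.transforms:
            p, outside = t.apply(p)
            n_outside += outside
        return p, n_outside

    def to_json(self, path: str | Path) -> None:
        items = []
        for t in self.transforms:
            if isinstance(t, Affine):
                items.append({"type": "affine", "matrix": t.matrix.tolist()})
            else:
                raise ValueError("only affine transforms serialize to JSON; save fields as volumes")
        Path(path).write_text(json.dumps({"direction": "native_to_atlas", "transforms": items}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformChain":
        d = json.loads(Path(path).read_text())
        return cls([Affine(np.asarray(t["matrix"])) for t in d["transforms"]])


@dataclass
class CountsVolume:
    """Atlas-geometry grid of native axon-voxel counts, plus out-of-bounds tally."""

    grid: np.ndarray
    out_of_bounds_count: int = 0
    voxel_size_um: float = 25.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("counts grid must be 3D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("counts grid must be integer")
        if self.grid.min() < 0 or self.out_of_bounds_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.grid.sum())


@dataclass
class DensityMap:
    """Axon voxels per labeled neuron per 25 µm atlas voxel, with metadata."""

    grid: np.ndarray
    n_cells: int
    voxel_size_um: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("density grid must be 3D")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be a positive integer, got {self.n_cells}")

    @property
    def total(self) -> float:
        return float(self.grid.sum())


@dataclass
class InjectionQC:
    """Injection-site centroid, target fraction and inclusion verdict."""

    center_voxel: tuple[float, float, float]
    fraction_in_targets: float
    included: bool
    volume_mm3: float
    n_voxels: int
    target_acronyms: tuple[str, ...]
    min_fraction: float


# ---------------------------------------------------------------------- #


def transform_coords(
    coords: pd.DataFrame | np.ndarray,
    chain: TransformChain,
    native_voxel_size_um: Sequence[float],
    atlas_voxel_size_um: float = 25.0,
) -> tuple[np.ndarray, dict]:
    """Map native voxel coordinates into real-valued atlas voxel coordinates.

    Native voxel indices are scaled to µm per axis, passed through the
    transform chain, and divided by the atlas voxel size.  Returns the
    (N, 3) atlas coordinates and an info dict with the out-of-support tally
    from any displacement fields.
    """
    if isinstance(coords, pd.DataFrame):
        pts = coords[["ap", "dv", "ml"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    native_um = pts * np.asarray(native_voxel_size_um, dtype=float)
    atlas_um, n_outside = chain.apply(native_um)
    out = atlas_um / float(atlas_voxel_size_um)
    if len(out) != len(pts):
        raise AssertionError("transform changed the number of coordinates")
    return out, {"out_of_support": n_outside}


def bin_to_atlas(atlas_coords: np.ndarray, annotation: AnnotationVolume) -> CountsVolume:
    """Bin real atlas coordinates to integer voxels, conserving counts exactly.

    Each coordinate is rounded half-up per axis (``floor(x + 0.5)``); counts
    falling outside the annotation grid are tallied, never dropped silently.
    """
    pts = np.asarray(atlas_coords, dtype=float).reshape(-1, 3)
    idx = np.floor(pts + 0.5).astype(np.int64)
    shape = np.asarray(annotation.shape)
    in_bounds = np.all((idx >= 0) & (idx < shape), axis=1)
    grid = np.zeros(annotation.shape, dtype=np.int64)
    kept = idx[in_bounds]
    if len(kept):
        np.add.at(grid, tuple(kept.T), 1)
    out = CountsVolume(
        grid=grid,
        out_of_bounds_count=int(len(pts) - in_bounds.sum()),
        voxel_size_um=annotation.voxel_size_um,
    )
    assert out.total + out.out_of_bounds_count == len(pts)
    return out


def normalize_per_cell(counts: CountsVolume, n_cells: int, meta: dict | None = None) -> DensityMap:
    """Divide every voxel by the number of labeled neurons at the injection."""
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    meta = dict(meta or {})
    meta.setdefault("out_of_bounds_count", counts.out_of_bounds_count)
    meta.setdefault("counts_total", counts.total)
    return DensityMap(
        grid=counts.grid.astype(float) / n_cells,
        n_cells=int(n_cells),
        voxel_size_um=counts.voxel_size_um,
        meta=meta,
    )


def injection_qc(
    mask: np.ndarray,
    annotation: AnnotationVolume,
    graph: StructureGraph,
    target_acronyms: Sequence[str] = ("SSp-bfd", "SSs"),
    min_fraction: float = 0.8,
) -> InjectionQC:
    """Locate the injection site and apply the target-fraction inclusion rule.

    A sample is included iff at least ``min_fraction`` (default 80%) of its
    injection-site voxels carry the ID of a target structure or any of its
    descendants (e.g. cortical layers).  The centroid is the unweighted mean
    of mask voxel indices.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != annotation.shape:
        raise ValueError("injection mask must share the annotation geometry")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("injection mask is empty")
    target_ids: set[int] = set()
    for acr in target_acronyms:
        target_ids.update(graph.self_and_descendants(graph.id_of(acr)))
    ids_in_mask = annotation.id_grid[mask]
    frac = float(np.isin(ids_in_mask, sorted(target_ids)).mean())
    center = tuple(float(c) for c in np.argwhere(mask).mean(axis=0))
    voxel_mm = annotation.voxel_size_um / 1000.0
    return InjectionQC(
        center_voxel=center,  # type: ignore[arg-type]
        fraction_in_targets=frac,
        included=bool(frac >= min_fraction),
        volume_mm3=n * voxel_mm**3,
        n_voxels=n,
        target_acronyms=tuple(target_acronyms),
        min_fraction=float(min_fraction),
    )


def group_average(maps: Sequence[DensityMap]) -> DensityMap:
    """Voxel-wise arithmetic mean across samples of identical geometry."""
    if not maps:
        raise ValueError("group_average requires at least one map")
    shape = maps[0].grid.shape
    vox = maps[0].voxel_size_um
    for m in maps[1:]:
        if m.grid.shape != shape or m.voxel_size_um != vox:
            raise ValueError("density maps have mismatched geometry")
    mean = np.mean([m.grid for m in maps], axis=0)
    return DensityMap(
        grid=mean,
        n_cells=1,
        voxel_size_um=vox,
        meta={
            "kind": "group_average",
            "n_samples": len(maps),
            "contributors": [m.meta.get("sample_id") for m in maps],
            "contributor_n_cells": [m.n_cells for m in maps],
        },
    )


def sum_projection(
    volume: DensityMap | CountsVolume | np.ndarray,
    axis: str | int,
    slab: tuple[int, int] | None = None,
) -> np.ndarray:
    """Sum the volume along one anatomical axis, optionally over a slab.

    ``slab`` is a half-open voxel index range along the projection axis
    (e.g. 5 planes for a 125 µm slab at 25 µm voxels); the 2D total equals
    the slab's 3D total exactly.
    """
    grid = volume.grid if hasattr(volume, "grid") else np.asarray(volume)
    if isinstance(axis, str):
        try:
            ax = AXIS_NAMES.index(axis)
        except ValueError:
            raise ValueError(f"axis must be one of {AXIS_NAMES}, got {axis!r}") from None
    else:
        ax = int(axis)
    if ax not in (AP, DV, ML):
        raise ValueError(f"axis index must be 0, 1 or 2, got {ax}")
    if slab is not None:
        lo, hi = slab
        if not (0 <= lo < hi <= grid.shape[ax]):
            raise ValueError(f"slab {slab} empty or outside axis extent {grid.shape[ax]}")
        sl = [slice(None)] * 3
        sl[ax] = slice(lo, hi)
        grid = grid[tuple(sl)]
    return grid.sum(axis=ax)
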