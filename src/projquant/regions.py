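"""Per-region, per-hemisphere quantification of axon density maps.

Every atlas voxel of a density map is accrued to its annotated structure at
the finest parcellation level (cortical layers, etc.) and to a hemisphere
bucket — ipsilateral, contralateral, or midline — relative to the injection
side.  Voxels annotated 0 (outside the parcellation) go to an explicit
``unassigned`` row, so the table always partitions the map total exactly.
Layer rows can then be rolled up the structure hierarchy (layers of a
cortical area sum to the area itself), and regions are ranked by mean
density across group averages and both hemispheres, keeping the top 75.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import ML, AnnotationVolume, CoordinateFrame, StructureGraph
from .density import DensityMap

HEMISPHERES = ("ipsi", "contra", "midline")
UNASSIGNED_ID = 0
UNASSIGNED_ACRONYM = "unassigned"

__all__ = [
    "HEMISPHERES",
    "UNASSIGNED_ID",
    "UNASSIGNED_ACRONYM",
    "quantify_by_region",
    "rollup_layers",
    "rank_regions",
    "table_total",
    "log_display_values",
]


def _hemisphere_codes(n_ml: int, frame: CoordinateFrame, injection_side: str) -> np.ndarray:
    """Per-ML-column code: 0 = ipsi, 1 = contra, 2 = midline."""
    if injection_side not in ("left", "right"):
        raise ValueError(f"injection_side must be 'left' or 'right', got {injection_side!r}")
    cols = np.arange(n_ml, dtype=float)
    d = cols - frame.midline_ml
    codes = np.full(n_ml, 1, dtype=np.int64)
    is_mid = np.abs(d) < 0.5
    is_left = d < 0
    ipsi = is_left if injection_side == "left" else ~is_left
    codes[ipsi] = 0
    codes[is_mid] = 2
    return codes


def quantify_by_region(
    dmap: DensityMap,
    annotation: AnnotationVolume,
    graph: StructureGraph,
    frame: CoordinateFrame,
    injection_side: str,
) -> pd.DataFrame:
    """Accrue a density map into a per-(structure, hemisphere) table.

    Returns a DataFrame with columns ``structure_id, acronym, hemisphere,
    axon_total, voxel_count``: one row for every leaf structure of the
    graph crossed with the three hemisphere buckets, plus ``unassigned``
    rows for voxels with annotation ID 0.  ``axon_total`` is in density
    units (axon voxels per neuron); ``voxel_count`` counts atlas voxels
    with nonzero density.  The rows partition the map total exactly.
    """
    if dmap.grid.shape != annotation.shape:
        raise ValueError("density map and annotation have mismatched geometry")
    annotation.validate_against(graph)

    hemi_cols = _hemisphere_codes(annotation.shape[ML], frame, injection_side)

    # composite key id*3 + hemisphere, accumulated with bincount
    id_grid = annotation.id_grid.astype(np.int64)
    key = id_grid * 3 + hemi_cols[np.newaxis, np.newaxis, :]
    key_flat = key.ravel()
    nbins = int(key_flat.max()) + 1
    totals = np.bincount(key_flat, weights=dmap.grid.ravel(), minlength=nbins)
    occupied = np.bincount(key_flat[dmap.grid.ravel() > 0], minlength=nbins)

    leaf_ids = graph.leaf_ids()
    row_ids = [UNASSIGNED_ID, *leaf_ids]
    rows = []
    for sid in row_ids:
        acr = UNASSIGNED_ACRONYM if sid == UNASSIGNED_ID else graph.acronym(sid)
        for h, hemi in enumerate(HEMISPHERES):
            k = sid * 3 + h
            rows.append(
                {
                    "structure_id": sid,
                    "acronym": acr,
                    "hemisphere": hemi,
                    "axon_total": float(totals[k]) if k < nbins else 0.0,
                    "voxel_count": int(occupied[k]) if k < nbins else 0,
                }
            )
    table = pd.DataFrame(rows)

    # any nonzero-ID voxel not in a graph leaf would break the partition
    accounted = table["axon_total"].sum()
    if not np.isclose(accounted, dmap.total, rtol=1e-12, atol=1e-9):
        raise AssertionError(
            f"region table ({accounted}) does not partition the map total ({dmap.total})"
        )
    table.attrs.update(
        {
            "injection_side": injection_side,
            "midline_rule": "voxels within 0.5 voxel of the midplane form a separate bucket",
            "rollup_levels": 0,
            **{k: v for k, v in dmap.meta.items() if np.isscalar(v) or v is None},
        }
    )
    return table


def rollup_layers(table: pd.DataFrame, graph: StructureGraph, levels: int = 1) -> pd.DataFrame:
    """Replace each structure by its ancestor ``levels`` steps up and re-sum.

    Layer rows of a cortical area collapse onto the area itself at
    ``levels=1``.  Rollup is capped at each structure's root, so repeated
    application converges; the ``unassigned`` bucket is left untouched.
    Totals are conserved exactly at every level.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    if levels == 0:
        out = table.copy()
        out.attrs.update(table.attrs)
        return out
    new_ids = []
    for sid in table["structure_id"]:
        if sid == UNASSIGNED_ID:
            new_ids.append(UNASSIGNED_ID)
        else:
            if sid not in graph:
                raise KeyError(f"unknown structure id {sid} in region table")
            new_ids.append(graph.ancestor_at(int(sid), levels))
    work = table.assign(structure_id=new_ids)
    grouped = (
        work.groupby(["structure_id", "hemisphere"], as_index=False, sort=False)
        .agg(axon_total=("axon_total", "sum"), voxel_count=("voxel_count", "sum"))
    )
    grouped["acronym"] = [
        UNASSIGNED_ACRONYM if sid == UNASSIGNED_ID else graph.acronym(int(sid))
        for sid in grouped["structure_id"]
    ]
    out = grouped[["structure_id", "acronym", "hemisphere", "axon_total", "voxel_count"]]
    out = out.sort_values(["structure_id", "hemisphere"], kind="mergesort").reset_index(drop=True)
    out.attrs.update(table.attrs)
    out.attrs["rollup_levels"] = int(table.attrs.get("rollup_levels", 0)) + levels
    return out


def table_total(table: pd.DataFrame) -> float:
    """Sum of all rows, including unassigned and midline buckets."""
    return float(table["axon_total"].sum())


def rank_regions(
    group_tables: Sequence[pd.DataFrame],
    top_n: int = 75,
) -> pd.DataFrame:
    """Rank anatomical regions by mean density across groups and hemispheres.

    For every region appearing in any table, the mean of its ``axon_total``
    is taken over all (group, hemisphere ∈ {ipsi, contra}) combinations,
    with missing entries counted as 0.  Midline and unassigned buckets are
    excluded from ranking (they are bookkeeping, not anatomy).  Regions are
    sorted by descending mean, ties broken by acronym, and truncated to
    ``top_n``.
    """
    if not group_tables:
        raise ValueError("rank_regions requires at least one table")
    frames = []
    for g, t in enumerate(group_tables):
        sub = t[(t["hemisphere"].isin(["ipsi", "contra"])) & (t["structure_id"] != UNASSIGNED_ID)]
        frames.append(sub.assign(group=g))
    allrows = pd.concat(frames, ignore_index=True)
    wide = allrows.pivot_table(
        index="acronym", columns=["group", "hemisphere"], values="axon_total",
        aggfunc="sum", fill_value=0.0,
    )
    # every table contributes exactly 2 hemisphere columns to the mean
    n_cols = 2 * len(group_tables)
    mean = wide.sum(axis=1) / n_cols
    ranking = (
        mean.rename("mean_density")
        .reset_index()
        .sort_values(["mean_density", "acronym"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
        .head(top_n)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def log_display_values(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation-only log10 scaling of region totals.

    Zeros are common and must remain zeros in stored tables; for display a
    pseudocount of one tenth of the smallest positive total is added before
    the log.  Never applied to stored data.
    """
    vals = table["axon_total"].to_numpy(dtype=float)
    positive = vals[vals > 0]
    if positive.size == 0:
        eps = 1.0
    else:
        eps = positive.min() / 10.0
    out = table.copy()
    out["log10_display"] = np.log10(vals + eps)
    return out
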