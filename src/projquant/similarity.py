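"""Cross-sample similarity of projection patterns.

Two complementary Pearson-correlation matrices compare injections:

* **categorical** — each sample is a vector of per-(leaf region ×
  hemisphere) axon totals at the finest parcellation level; correlation is
  computed between these region vectors, so it is blind to *where* inside a
  region the axons sit;
* **spatial** — each sample's 25 µm density map is smoothed with an
  isotropic 3D Gaussian (σ = 4 voxels, reflect boundary) and flattened;
  correlation between the flattened arrays captures voxel-level layout.

Samples are ordered first by transgenic line (a configured canonical
order), then by the absolute mediolateral position of the injection center,
most medial first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .density import DensityMap
from .regions import UNASSIGNED_ID

__all__ = [
    "CorrelationMatrix",
    "order_samples",
    "categorical_correlation",
    "spatial_correlation",
    "pairwise_pearson",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with its sample ordering and parameters."""

    matrix: np.ndarray
    labels: list[str]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix must be square and match the label list")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def order_samples(
    metadata: pd.DataFrame,
    line_order: Sequence[str],
) -> list[str]:
    """Canonical sample ordering: by line, then |ML| of injection, medial first.

    ``metadata`` needs columns ``sample_id``, ``cre_line`` and
    ``injection_ml_mm`` (signed, bregma-referenced).  The sort is stable,
    so the result is invariant to the input permutation.
    """
    required = {"sample_id", "cre_line", "injection_ml_mm"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"sample metadata missing column(s): {sorted(missing)}")
    if metadata[list(required)].isna().any().any():
        bad = metadata.loc[metadata[list(required)].isna().any(axis=1), "sample_id"].tolist()
        raise ValueError(f"sample(s) with missing metadata: {bad}")
    line_rank = {line: i for i, line in enumerate(line_order)}
    unknown = sorted(set(metadata["cre_line"]) - set(line_rank))
    if unknown:
        raise ValueError(f"cre line(s) not in canonical order: {unknown}")
    work = metadata.assign(
        _line=metadata["cre_line"].map(line_rank),
        _ml=metadata["injection_ml_mm"].abs(),
    )
    work = work.sort_values(["_line", "_ml", "sample_id"], kind="mergesort")
    return work["sample_id"].tolist()


def pairwise_pearson(vectors: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Pearson r between rows; zero-variance rows marked NaN, not silently 0.

    Returns the matrix and the indices of degenerate (constant) rows.  The
    diagonal is 1 everywhere, including degenerate rows, by convention.
    """
    v = np.asarray(vectors, dtype=float)
    centered = v - v.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = [int(i) for i in np.flatnonzero(norms == 0)]
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, np.newaxis]
    r = unit @ unit.T
    r = np.clip(r, -1.0, 1.0)
    for i in degenerate:
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    return r, degenerate


def categorical_correlation(
    tables: Mapping[str, pd.DataFrame],
    order: Sequence[str],
) -> CorrelationMatrix:
    """Region-level Pearson correlation between samples.

    Each sample's vector concatenates its ipsi and contra per-leaf-region
    totals (hemispheres kept separate); region/hemisphere combinations
    missing from a table count as 0.  Midline and unassigned buckets are
    excluded.
    """
    keys: set[tuple[int, str]] = set()
    for t in tables.values():
        sub = t[(t["hemisphere"].isin(["ipsi", "contra"])) & (t["structure_id"] != UNASSIGNED_ID)]
        keys.update(zip(sub["structure_id"].astype(int), sub["hemisphere"]))
    universe = sorted(keys)
    index = {k: i for i, k in enumerate(universe)}
    vectors = np.zeros((len(order), len(universe)))
    for row, sid in enumerate(order):
        t = tables[sid]
        sub = t[(t["hemisphere"].isin(["ipsi", "contra"])) & (t["structure_id"] != UNASSIGNED_ID)]
        for s, h, v in zip(sub["structure_id"].astype(int), sub["hemisphere"], sub["axon_total"]):
            vectors[row, index[(s, h)]] = v
    r, degenerate = pairwise_pearson(vectors)
    return CorrelationMatrix(
        matrix=r,
        labels=list(order),
        method="categorical",
        params={
            "n_features": len(universe),
            "hemispheres": "ipsi+contra concatenated",
            "degenerate_samples": [order[i] for i in degenerate],
        },
    )


def spatial_correlation(
    maps: Mapping[str, DensityMap],
    order: Sequence[str],
    sigma_voxels: float = 4.0,
) -> CorrelationMatrix:
    """Voxel-level Pearson correlation between Gaussian-filtered maps.

    Each map is smoothed with an isotropic 3D Gaussian (σ in voxels,
    reflect boundary — the common scientific default, recorded in the
    matrix metadata) and flattened before pairwise correlation.  σ = 0
    reduces to raw-voxel correlation.
    """
    shapes = {maps[s].grid.shape for s in order}
    if len(shapes) != 1:
        raise ValueError(f"density maps have mismatched geometry: {sorted(shapes)}")
    vectors = np.empty((len(order), int(np.prod(next(iter(shapes))))))
    for row, sid in enumerate(order):
        g = maps[sid].grid
        if sigma_voxels > 0:
            g = ndimage.gaussian_filter(g, sigma=sigma_voxels, mode="reflect")
        vectors[row] = g.ravel()
    r, degenerate = pairwise_pearson(vectors)
    return CorrelationMatrix(
        matrix=r,
        labels=list(order),
        method="spatial",
        params={
            "sigma_voxels": float(sigma_voxels),
            "boundary": "reflect",
            "degenerate_samples": [order[i] for i in degenerate],
        },
    )
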