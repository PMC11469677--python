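"""Weighted skeletonization of probabilistic axon segmentations.

The segmentation network emits a per-voxel probability of containing axon.
A single binarization threshold either drops dim axons (high threshold) or
merges noise into thick blobs (low threshold).  The multi-threshold weighted
skeleton sidesteps this: the volume is binarized at eight thresholds from
0.2 to 0.9 in steps of 0.1, each binary stack is skeletonized independently,
each skeleton is scaled by its threshold, and the eight scaled skeletons are
summed.  Voxels supported at many thresholds accumulate weight (maximum
0.2 + 0.3 + ... + 0.9 = 4.4); dim-but-real axons survive through the low
thresholds.  Downstream quantification treats every skeleton voxel as one
axon-containing voxel regardless of weight; the weight is construction
scaffolding and provenance, retained as metadata only.

Artifact removal follows: connected components (26-connectivity) smaller
than 10,000 voxels are discarded, and the survivors can be curated with an
explicit keep/drop decision file before export to a coordinate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _skeletonize

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
#: native voxel size of the light-sheet stacks, (AP, DV, ML) in µm
DEFAULT_NATIVE_VOXEL_UM: tuple[float, float, float] = (5.3, 5.3, 5.0)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_NATIVE_VOXEL_UM",
    "ProbabilityVolume",
    "AxonSkeleton",
    "CurationDecision",
    "weighted_skeleton",
    "filter_components",
    "apply_curation",
    "skeleton_to_coords",
    "write_coords",
    "read_coords",
]


@dataclass
class ProbabilityVolume:
    """3D grid of axon probabilities in [0, 1] at native resolution."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_NATIVE_VOXEL_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("probability volume must be 3D")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < 0.0 or vmax > 1.0:
            raise ValueError(f"probabilities must lie in [0, 1], got range [{vmin}, {vmax}]")
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be a positive triple")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class AxonSkeleton:
    """Sparse weighted skeleton: voxel coordinates, weights, component labels.

    ``coords`` is an (N, 3) integer array in canonical (AP, DV, ML) voxel
    order, lexicographically sorted.  ``weights`` are sums of the thresholds
    at which each voxel appeared in a per-threshold skeleton.
    ``component_sizes`` maps each component label to its voxel count.
    """

    coords: np.ndarray
    weights: np.ndarray
    component_ids: np.ndarray
    component_sizes: dict[int, int]
    shape: tuple[int, int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.component_ids = np.asarray(self.component_ids, dtype=np.int64).reshape(-1)
        n = len(self.coords)
        if len(self.weights) != n or len(self.component_ids) != n:
            raise ValueError("coords, weights and component_ids must have equal length")
        sizes = {int(k): int(v) for k, v in self.component_sizes.items()}
        if n:
            counts = dict(zip(*np.unique(self.component_ids, return_counts=True)))
            counts = {int(k): int(v) for k, v in counts.items()}
            if counts != sizes:
                raise ValueError("component_sizes inconsistent with component_ids")
        elif sizes:
            raise ValueError("component_sizes nonempty for empty skeleton")
        self.component_sizes = sizes

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def to_dense_weights(self) -> np.ndarray:
        """Dense float volume of per-voxel weights (0 where no skeleton)."""
        out = np.zeros(self.shape, dtype=float)
        if self.n_voxels:
            out[tuple(self.coords.T)] = self.weights
        return out


@dataclass
class CurationDecision:
    """Explicit keep/drop verdict per component, with free-text reasons.

    Curation in the original workflow is a manual inspection step; here it
    is a file, so any external viewer can be used and the decision trail is
    preserved in the skeleton's provenance.
    """

    decisions: dict[int, str]
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, verdict in self.decisions.items():
            if verdict not in ("keep", "drop"):
                raise ValueError(f"decision for component {label} must be keep|drop, got {verdict!r}")


# ---------------------------------------------------------------------- #


def _label_voxels(coords: np.ndarray, shape: tuple[int, int, int]) -> tuple[np.ndarray, dict[int, int]]:
    """26-connected component label per coordinate row, sizes per label."""
    if len(coords) == 0:
        return np.empty(0, dtype=np.int64), {}
    dense = np.zeros(shape, dtype=bool)
    dense[tuple(coords.T)] = True
    labeled, n = ndimage.label(dense, structure=np.ones((3, 3, 3), dtype=bool))
    labels = labeled[tuple(coords.T)].astype(np.int64)
    ids, counts = np.unique(labels, return_counts=True)
    return labels, {int(i): int(c) for i, c in zip(ids, counts)}


def weighted_skeleton(
    prob: ProbabilityVolume,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> AxonSkeleton:
    """Multi-threshold weighted skeleton of a probability volume.

    For each threshold ``t`` (strictly increasing, each in (0, 1)) the
    volume is binarized at ``prob >= t``, skeletonized by 3D medial-axis
    thinning, scaled by ``t``, and the scaled skeletons are summed.  The
    per-threshold masks are nested by construction; this is asserted before
    thinning.  Thinning operates on the voxel lattice, ignoring anisotropy
    (which is carried in metadata for physical-unit conversions downstream).
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError(f"thresholds must lie in (0, 1), got {thresholds}")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")

    weight = np.zeros(prob.shape, dtype=float)
    prev_mask: np.ndarray | None = None
    for t in thresholds:
        mask = prob.values >= t
        if prev_mask is not None and np.any(mask & ~prev_mask):
            raise AssertionError("per-threshold masks are not nested")
        prev_mask = mask
        if mask.any():
            weight += t * _skeletonize(mask).astype(bool)

    coords = np.argwhere(weight > 0)  # lexicographic order by construction
    weights = weight[tuple(coords.T)] if len(coords) else np.empty(0)
    labels, sizes = _label_voxels(coords, prob.shape)
    return AxonSkeleton(
        coords=coords,
        weights=weights,
        component_ids=labels,
        component_sizes=sizes,
        shape=prob.shape,
        provenance={"thresholds": list(thresholds), "voxel_size_um": list(prob.voxel_size_um)},
    )


def filter_components(
    skel: AxonSkeleton,
    min_size: int = 10_000,
    connectivity: int = 26,
) -> tuple[AxonSkeleton, pd.DataFrame]:
    """Remove components strictly smaller than ``min_size`` voxels.

    Survivors are relabeled 1, 2, ... by descending size (ties broken by the
    previous label, so the operation is idempotent and deterministic).  The
    report lists every input component's size and fate.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    order = sorted(skel.component_sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    report = pd.DataFrame(
        {
            "component": [k for k, _ in order],
            "size": [v for _, v in order],
            "kept": [v >= min_size for _, v in order],
        }
    )
    keep_labels = [k for k, v in order if v >= min_size]
    relabel = {old: new for new, old in enumerate(keep_labels, start=1)}
    mask = np.isin(skel.component_ids, keep_labels)
    new_ids = np.array([relabel[c] for c in skel.component_ids[mask]], dtype=np.int64)
    out = AxonSkeleton(
        coords=skel.coords[mask],
        weights=skel.weights[mask],
        component_ids=new_ids,
        component_sizes={relabel[k]: skel.component_sizes[k] for k in keep_labels},
        shape=skel.shape,
        provenance={**skel.provenance, "min_component_size": int(min_size)},
    )
    return out, report


def apply_curation(skel: AxonSkeleton, decisions: CurationDecision) -> AxonSkeleton:
    """Drop components marked ``drop``; persist the decision trail."""
    unknown = [l for l in decisions.decisions if l not in skel.component_sizes]
    if unknown:
        raise KeyError(f"curation references unknown component label(s) {unknown}")
    drop = {l for l, v in decisions.decisions.items() if v == "drop"}
    mask = ~np.isin(skel.component_ids, sorted(drop))
    kept_labels = sorted(set(skel.component_sizes) - drop)
    return AxonSkeleton(
        coords=skel.coords[mask],
        weights=skel.weights[mask],
        component_ids=skel.component_ids[mask],
        component_sizes={l: skel.component_sizes[l] for l in kept_labels},
        shape=skel.shape,
        provenance={
            **skel.provenance,
            "curation": {
                "decisions": {int(k): v for k, v in sorted(decisions.decisions.items())},
                "reasons": {int(k): v for k, v in sorted(decisions.reasons.items())},
            },
        },
    )


def skeleton_to_coords(skel: AxonSkeleton) -> pd.DataFrame:
    """Export the skeleton as an ordered coordinate list.

    One row per voxel, lexicographically sorted on (AP, DV, ML); the weight
    and component columns ride along as metadata.
    """
    order = np.lexsort((skel.coords[:, 2], skel.coords[:, 1], skel.coords[:, 0]))
    df = pd.DataFrame(
        {
            "ap": skel.coords[order, 0],
            "dv": skel.coords[order, 1],
            "ml": skel.coords[order, 2],
            "weight": skel.weights[order],
            "component": skel.component_ids[order],
        }
    )
    df.attrs["shape"] = tuple(skel.shape)
    df.attrs.update(skel.provenance)
    return df


def write_coords(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, index=False)


def read_coords(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
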