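"""Atlas data model: annotation volume, structure hierarchy and stereotaxic frame.

All volumes in this package use one canonical axis order, ``(AP, DV, ML)``:

* axis 0 — anteroposterior, index increasing **posteriorly**;
* axis 1 — dorsoventral, index increasing **ventrally**;
* axis 2 — mediolateral, index increasing **rightward**.

Physical coordinates are reported in millimetres relative to bregma with
anterior, ventral and right positive.  The bregma voxel and the mediolateral
index of the sagittal midplane are configuration carried by
:class:`CoordinateFrame`, never constants, because toy and real atlases
differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

AP, DV, ML = 0, 1, 2
AXIS_NAMES = ("AP", "DV", "ML")

__all__ = [
    "AP",
    "DV",
    "ML",
    "AXIS_NAMES",
    "CoordinateFrame",
    "StructureGraph",
    "AnnotationVolume",
    "load_structure_graph",
    "voxel_to_bregma_mm",
    "bregma_mm_to_voxel",
    "hemisphere_of",
]


@dataclass(frozen=True)
class CoordinateFrame:
    """Mapping between voxel indices and bregma-referenced millimetres.

    Parameters
    ----------
    bregma_voxel
        Real-valued ``(AP, DV, ML)`` voxel indices of bregma.
    midline_ml
        Real ML voxel index of the sagittal midplane.
    voxel_size_um
        Isotropic voxel edge length in micrometres (25 for the reference
        atlas resolution used throughout).
    """

    bregma_voxel: tuple[float, float, float]
    midline_ml: float
    voxel_size_um: float = 25.0

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if len(self.bregma_voxel) != 3:
            raise ValueError("bregma_voxel must be an (AP, DV, ML) triple")

    # ------------------------------------------------------------------ #
    def voxel_to_bregma_mm(self, coord: Sequence[float] | np.ndarray) -> np.ndarray:
        """Convert voxel indices to (AP_mm, DV_mm, ML_mm) relative to bregma.

        Anterior is positive AP (indices grow posteriorly, hence the sign
        flip), ventral is positive DV, right of the midline is positive ML.
        Pure affine map; coordinates outside the grid are allowed.
        """
        c = np.asarray(coord, dtype=float)
        scale = self.voxel_size_um / 1000.0
        out = np.empty_like(c)
        out[..., AP] = (self.bregma_voxel[AP] - c[..., AP]) * scale
        out[..., DV] = (c[..., DV] - self.bregma_voxel[DV]) * scale
        out[..., ML] = (c[..., ML] - self.midline_ml) * scale
        return out

    def bregma_mm_to_voxel(self, mm: Sequence[float] | np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_bregma_mm`."""
        m = np.asarray(mm, dtype=float)
        scale = 1000.0 / self.voxel_size_um
        out = np.empty_like(m)
        out[..., AP] = self.bregma_voxel[AP] - m[..., AP] * scale
        out[..., DV] = self.bregma_voxel[DV] + m[..., DV] * scale
        out[..., ML] = self.midline_ml + m[..., ML] * scale
        return out

    # ------------------------------------------------------------------ #
    def side_of(self, coord: Sequence[float] | np.ndarray) -> str | np.ndarray:
        """Return ``left``/``right``/``midline`` for voxel coordinate(s).

        Coordinates within half a voxel of the midplane are assigned to a
        separate midline bucket so that left + right + midline always
        partitions any total.
        """
        c = np.asarray(coord, dtype=float)
        d = c[..., ML] - self.midline_ml
        labels = np.where(np.abs(d) < 0.5, "midline", np.where(d < 0, "left", "right"))
        if labels.ndim == 0:
            return str(labels)
        return labels

    def hemisphere_of(
        self, coord: Sequence[float] | np.ndarray, injection_side: str
    ) -> str | np.ndarray:
        """Classify coordinate(s) as ``ipsi``/``contra``/``midline``.

        ``injection_side`` is ``"left"`` or ``"right"``; a coordinate is
        ipsilateral iff it falls on the injection side of the midplane.
        """
        if injection_side not in ("left", "right"):
            raise ValueError(f"injection_side must be 'left' or 'right', got {injection_side!r}")
        side = self.side_of(coord)
        arr = np.asarray(side)
        out = np.where(
            arr == "midline", "midline", np.where(arr == injection_side, "ipsi", "contra")
        )
        if out.ndim == 0:
            return str(out)
        return out

    def to_dict(self) -> dict:
        return {
            "bregma_voxel": list(self.bregma_voxel),
            "midline_ml": self.midline_ml,
            "voxel_size_um": self.voxel_size_um,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoordinateFrame":
        return cls(
            bregma_voxel=tuple(float(x) for x in d["bregma_voxel"]),
            midline_ml=float(d["midline_ml"]),
            voxel_size_um=float(d["voxel_size_um"]),
        )


class StructureGraph:
    """Hierarchy of brain structures: a forest of (id, acronym, name, parent).

    Mirrors the structure-graph dialect of the Allen CCF: a flat JSON list of
    nodes, each carrying an integer ``id``, a short ``acronym``, a ``name``
    and a ``parent_id`` (``None`` for roots).  Validation enforces unique
    IDs and acronyms, resolvable parents and acyclicity.
    """

    def __init__(self, nodes: Iterable[Mapping]) -> None:
        nodes = [dict(n) for n in nodes]
        if not nodes:
            raise ValueError("structure graph has no nodes")
        self._by_id: dict[int, dict] = {}
        acronyms: dict[str, int] = {}
        for n in nodes:
            nid = int(n["id"])
            if nid in self._by_id:
                raise ValueError(f"duplicate structure id {nid}")
            acr = str(n["acronym"])
            if acr in acronyms:
                raise ValueError(f"duplicate acronym {acr!r} (ids {acronyms[acr]} and {nid})")
            acronyms[acr] = nid
            self._by_id[nid] = {
                "id": nid,
                "acronym": acr,
                "name": str(n.get("name", acr)),
                "parent_id": None if n.get("parent_id") is None else int(n["parent_id"]),
            }
        self._by_acronym = acronyms
        self._children: dict[int, list[int]] = {nid: [] for nid in self._by_id}
        for n in self._by_id.values():
            pid = n["parent_id"]
            if pid is not None:
                if pid not in self._by_id:
                    raise ValueError(
                        f"node {n['id']} ({n['acronym']!r}) has dangling parent_id {pid}"
                    )
                self._children[pid].append(n["id"])
        # cycle check: walk to root from every node
        for nid in self._by_id:
            seen = set()
            cur: int | None = nid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in structure graph involving node {cur}")
                seen.add(cur)
                cur = self._by_id[cur]["parent_id"]

    # ------------------------------------------------------------------ #
    @property
    def ids(self) -> list[int]:
        return sorted(self._by_id)

    @property
    def roots(self) -> list[int]:
        return sorted(n["id"] for n in self._by_id.values() if n["parent_id"] is None)

    def node(self, structure_id: int) -> dict:
        try:
            return self._by_id[structure_id]
        except KeyError:
            raise KeyError(f"unknown structure id {structure_id}") from None

    def acronym(self, structure_id: int) -> str:
        return self.node(structure_id)["acronym"]

    def id_of(self, acronym: str) -> int:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise KeyError(f"unknown acronym {acronym!r}") from None

    def parent(self, structure_id: int) -> int | None:
        return self.node(structure_id)["parent_id"]

    def children(self, structure_id: int) -> list[int]:
        self.node(structure_id)
        return sorted(self._children[structure_id])

    def is_leaf(self, structure_id: int) -> bool:
        return not self._children[self.node(structure_id)["id"]]

    def ancestors(self, structure_id: int) -> list[int]:
        """Ancestor chain from immediate parent up to the root."""
        out = []
        cur = self.parent(structure_id)
        while cur is not None:
            out.append(cur)
            cur = self.parent(cur)
        return out

    def ancestor_at(self, structure_id: int, levels: int) -> int:
        """The ancestor ``levels`` steps above a node, capped at its root."""
        if levels < 0:
            raise ValueError("levels must be >= 0")
        cur = self.node(structure_id)["id"]
        for _ in range(levels):
            pid = self.parent(cur)
            if pid is None:
                break
            cur = pid
        return cur

    def descendants(self, structure_id: int) -> list[int]:
        """All strict descendants of a node."""
        out: list[int] = []
        stack = list(self._children[self.node(structure_id)["id"]])
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self._children[nid])
        return sorted(out)

    def self_and_descendants(self, structure_id: int) -> list[int]:
        return sorted([self.node(structure_id)["id"], *self.descendants(structure_id)])

    def leaf_ids(self) -> list[int]:
        return sorted(nid for nid in self._by_id if not self._children[nid])

    # ------------------------------------------------------------------ #
    def to_json(self, path: str | Path) -> None:
        nodes = [self._by_id[nid] for nid in self.ids]
        Path(path).write_text(json.dumps(nodes, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructureGraph":
        return cls(json.loads(Path(path).read_text()))

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, structure_id: int) -> bool:
        return structure_id in self._by_id


@dataclass
class AnnotationVolume:
    """3D grid of non-negative integer structure IDs (0 = outside brain)."""

    id_grid: np.ndarray
    voxel_size_um: float = 25.0

    def __post_init__(self) -> None:
        self.id_grid = np.asarray(self.id_grid)
        if self.id_grid.ndim != 3 or min(self.id_grid.shape) < 1:
            raise ValueError("annotation grid must be 3D with positive shape")
        if not np.issubdtype(self.id_grid.dtype, np.integer):
            raise ValueError("annotation grid must hold integers")
        if self.id_grid.min() < 0:
            raise ValueError("annotation grid must be non-negative")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.id_grid.shape  # type: ignore[return-value]

    def present_ids(self) -> np.ndarray:
        """Sorted nonzero structure IDs occurring in the grid."""
        ids = np.unique(self.id_grid)
        return ids[ids > 0]

    def validate_against(self, graph: StructureGraph) -> None:
        """Every nonzero ID in the grid must exist in the structure graph."""
        missing = [int(i) for i in self.present_ids() if int(i) not in graph]
        if missing:
            raise ValueError(f"annotation IDs absent from structure graph: {missing}")


# ---------------------------------------------------------------------- #
# module-level operation wrappers


def load_structure_graph(path: str | Path) -> StructureGraph:
    """Read and validate a structure-graph JSON file."""
    return StructureGraph.from_json(path)


def voxel_to_bregma_mm(coord, frame: CoordinateFrame) -> np.ndarray:
    return frame.voxel_to_bregma_mm(coord)


def bregma_mm_to_voxel(mm, frame: CoordinateFrame) -> np.ndarray:
    return frame.bregma_mm_to_voxel(mm)


def hemisphere_of(coord, frame: CoordinateFrame, injection_side: str):
    return frame.hemisphere_of(coord, injection_side)
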