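"""Synthetic inputs with complete ground truth.

Real inputs to the pipeline are light-sheet axon-probability volumes,
registration transforms, the reference atlas and wide-field movies.  This
module generates stand-ins for all of them with known ground truth, so
every downstream stage can be tested end-to-end and parameter recovery can
be measured:

* a **toy atlas**: a mirror-symmetric hierarchical parcellation containing
  the structures the analyses need (somatosensory injection targets
  SSp-bfd and SSs, motor areas MOp and MOs — each with cortical layers
  stacked along DV — and the caudoputamen CP), at 25 µm voxels on the
  canonical (AP, DV, ML) axes;
* **tube phantoms**: probability volumes built from known polyline
  centerlines with Gaussian cross-sections, plus bright edge-artifact
  blobs and additive noise, emulating segmentation-network output;
* **injection cohorts** whose motor-cortex hotspot centers obey a known
  mirror map ``AP = a + s·|ML|`` with configurable Gaussian scatter — the
  recovery target for the topography regression;
* **wide-field sessions** with a baseline fluorescence image,
  stimulus-evoked Gaussian hotspots whose centers follow the same mirror
  map, boxcar time courses and per-frame noise.

All generators are seed-deterministic and record their ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import AP, DV, ML, AnnotationVolume, CoordinateFrame, StructureGraph
from .density import DensityMap, TransformChain, Affine
from .skeleton import ProbabilityVolume, DEFAULT_NATIVE_VOXEL_UM
from .widefield import WidefieldSession

__all__ = [
    "LayerDef",
    "RegionDef",
    "AtlasSpec",
    "make_toy_atlas",
    "AxonTruth",
    "make_tube_truth",
    "simulate_axon_probability",
    "TopographySpec",
    "SampleTruth",
    "CohortTruth",
    "SyntheticSample",
    "simulate_injection_cohort",
    "WidefieldTruth",
    "SessionTruth",
    "simulate_widefield_session",
]


# ====================================================================== #
# toy atlas


@dataclass(frozen=True)
class LayerDef:
    """Cortical layer: acronym suffix and absolute DV extent in mm."""

    suffix: str
    dv_mm: tuple[float, float]


#: standard cortical laminar stack used by every toy cortical area
CORTICAL_LAYERS: tuple[LayerDef, ...] = (
    LayerDef("1", (0.0, 0.1)),
    LayerDef("2/3", (0.1, 0.4)),
    LayerDef("5", (0.4, 0.7)),
    LayerDef("6", (0.7, 1.0)),
)


@dataclass(frozen=True)
class RegionDef:
    """Hemisphere-symmetric cuboid region; layers subdivide it along DV.

    ``ap_mm`` is (posterior, anterior) edge in bregma mm; ``ml_abs_mm`` the
    (medial, lateral) absolute ML band, mirrored into both hemispheres;
    ``dv_mm`` the (dorsal, ventral) extent.  A region with ``ap_mm`` None
    is a pure container node (graph only, no voxels).
    """

    acronym: str
    parent: str
    ap_mm: tuple[float, float] | None = None
    ml_abs_mm: tuple[float, float] | None = None
    dv_mm: tuple[float, float] | None = None
    layers: tuple[LayerDef, ...] | None = None


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry and region list of the toy atlas."""

    shape: tuple[int, int, int] = (241, 101, 401)
    voxel_size_um: float = 25.0
    bregma_voxel: tuple[float, float, float] = (120.0, 0.0, 200.0)
    midline_ml: float = 200.0
    regions: tuple[RegionDef, ...] = (
        RegionDef("Isocortex", "root"),
        RegionDef("MOs", "Isocortex", (0.5, 2.75), (0.15, 1.0), (0.0, 1.0), CORTICAL_LAYERS),
        RegionDef("MOp", "Isocortex", (0.0, 2.75), (1.0, 2.3), (0.0, 1.0), CORTICAL_LAYERS),
        RegionDef("SSp-bfd", "Isocortex", (-2.5, -0.5), (2.4, 3.6), (0.0, 1.0), CORTICAL_LAYERS),
        RegionDef("SSs", "Isocortex", (-2.5, -0.5), (3.6, 4.6), (0.0, 1.0), CORTICAL_LAYERS),
        RegionDef("CP", "root", (-0.5, 1.5), (1.3, 2.8), (1.2, 2.2)),
    )

    def frame(self) -> CoordinateFrame:
        return CoordinateFrame(self.bregma_voxel, self.midline_ml, self.voxel_size_um)


def _index_range(lo: float, hi: float, origin: float, sign: float, k: float) -> tuple[int, int]:
    """Half-open voxel index range of a mm interval along one axis."""
    a = int(round(origin + sign * lo * k))
    b = int(round(origin + sign * hi * k))
    return (min(a, b), max(a, b))


def make_toy_atlas(
    spec: AtlasSpec | None = None,
) -> tuple[AnnotationVolume, StructureGraph, CoordinateFrame]:
    """Build the annotation volume, structure graph and frame from a spec.

    Every region voxel carries its *leaf* ID (layer where layers exist);
    left-hemisphere voxels are the exact mirror image of the right, so
    flipping the ML axis reproduces the grid.  Overlapping definitions
    raise an error naming the colliding pair.
    """
    spec = spec or AtlasSpec()
    k = 1000.0 / spec.voxel_size_um  # voxels per mm
    grid = np.zeros(spec.shape, dtype=np.int32)

    nodes: list[dict] = [{"id": 1, "acronym": "root", "name": "root", "parent_id": None}]
    id_of: dict[str, int] = {"root": 1}
    next_id = 2

    def fill_box(sid: int, acr: str, ap: tuple[float, float], dv: tuple[float, float],
                 ml_abs: tuple[float, float]) -> None:
        nonlocal grid
        ap0, ap1 = _index_range(ap[0], ap[1], spec.bregma_voxel[AP], -1.0, k)
        dv0, dv1 = _index_range(dv[0], dv[1], spec.bregma_voxel[DV], +1.0, k)
        off0, off1 = int(round(ml_abs[0] * k)), int(round(ml_abs[1] * k))
        if off0 < 1:
            raise ValueError(f"region {acr!r} touches the midline (offset {off0} voxels)")
        if not (0 <= ap0 < ap1 <= spec.shape[AP] and 0 <= dv0 < dv1 <= spec.shape[DV]):
            raise ValueError(f"region {acr!r} outside the grid along AP or DV")
        cols_right = np.arange(int(round(spec.midline_ml)) + off0,
                               int(round(spec.midline_ml)) + off1)
        cols_left = (2 * int(round(spec.midline_ml)) - cols_right)[::-1]
        if cols_right[-1] >= spec.shape[ML] or cols_left[0] < 0:
            raise ValueError(f"region {acr!r} outside the grid along ML")
        for cols in (cols_right, cols_left):
            block = grid[ap0:ap1, dv0:dv1, cols[0] : cols[-1] + 1]
            clash = block[block != 0]
            if clash.size:
                other = next(a for a, i in id_of.items() if i == int(clash[0]))
                raise ValueError(f"regions {acr!r} and {other!r} overlap")
            block[:] = sid

    for region in spec.regions:
        if region.parent not in id_of:
            raise ValueError(f"region {region.acronym!r} lists undefined parent {region.parent!r}")
        rid = next_id
        next_id += 1
        id_of[region.acronym] = rid
        nodes.append({"id": rid, "acronym": region.acronym, "name": region.acronym,
                      "parent_id": id_of[region.parent]})
        if region.ap_mm is None:
            continue
        if region.layers:
            for layer in region.layers:
                lid = next_id
                next_id += 1
                acr = f"{region.acronym}{layer.suffix}"
                id_of[acr] = lid
                nodes.append({"id": lid, "acronym": acr, "name": acr, "parent_id": rid})
                fill_box(lid, acr, region.ap_mm, layer.dv_mm, region.ml_abs_mm)  # type: ignore[arg-type]
        else:
            fill_box(rid, region.acronym, region.ap_mm, region.dv_mm, region.ml_abs_mm)  # type: ignore[arg-type]

    annotation = AnnotationVolume(grid, spec.voxel_size_um)
    graph = StructureGraph(nodes)
    annotation.validate_against(graph)
    return annotation, graph, spec.frame()


# ====================================================================== #
# axon phantoms


@dataclass
class AxonTruth:
    """Ground truth of a phantom: centerlines, tube geometry, artifacts."""

    centerlines: list[np.ndarray]
    radii: list[float]
    brightness: list[float]
    blobs: list[tuple[tuple[float, float, float], float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.centerlines) != len(self.radii) or len(self.radii) != len(self.brightness):
            raise ValueError("centerlines, radii and brightness must align")
        for r in self.radii:
            if r < 0.5:
                raise ValueError(f"tube radius must be >= 0.5 voxel, got {r}")


def make_tube_truth(
    shape: tuple[int, int, int],
    n_tubes: int = 2,
    n_steps: int = 150,
    radius: float = 1.0,
    brightness: float = 1.0,
    seed: int = 0,
    margin: int = 5,
    n_blobs: int = 0,
    blob_radius: float = 3.0,
    start_points: Sequence[Sequence[float]] | None = None,
) -> AxonTruth:
    """Random-walk tube centerlines (with momentum) inside a volume.

    Optional bright spherical blobs near the volume edges emulate the
    bright artifacts segmentation networks produce at the brain surface.
    """
    rng = np.random.default_rng(seed)
    lo = np.full(3, margin, dtype=float)
    hi = np.asarray(shape, dtype=float) - margin - 1
    centerlines = []
    for i in range(n_tubes):
        if start_points is not None:
            p = np.clip(np.asarray(start_points[i], dtype=float), lo, hi)
        else:
            p = rng.uniform(lo, hi)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = [p.copy()]
        # keep non-adjacent segments farther apart than the merge distance
        # of two Gaussian tube profiles, else the medial axis of the fused
        # blob no longer tracks either centerline
        min_self = 4.0 * radius
        lag = int(np.ceil(2 * min_self))
        for _ in range(n_steps):
            placed = False
            for _attempt in range(12):
                d2 = d + 0.2 * rng.normal(size=3)
                d2 /= np.linalg.norm(d2)
                p2 = p + d2
                # reflect at the walls so the walk cannot slide along a face
                # (clipping there would stack the tube into a plate)
                for ax in range(3):
                    if p2[ax] < lo[ax]:
                        p2[ax] = 2 * lo[ax] - p2[ax]
                        d2[ax] = -d2[ax]
                    elif p2[ax] > hi[ax]:
                        p2[ax] = 2 * hi[ax] - p2[ax]
                        d2[ax] = -d2[ax]
                past = pts[: -lag] if len(pts) > lag else []
                if past and np.min(np.linalg.norm(np.asarray(past) - p2, axis=1)) < min_self:
                    continue
                p, d = p2, d2
                pts.append(p.copy())
                placed = True
                break
            if not placed:
                break  # boxed in; end the tube rather than fuse it
        centerlines.append(np.asarray(pts))
    blobs = []
    for _ in range(n_blobs):
        # edge artifacts: pin one coordinate near a face of the volume
        c = rng.uniform(lo, hi)
        axis = int(rng.integers(3))
        c[axis] = float(rng.choice([margin, shape[axis] - margin - 1]))
        blobs.append((tuple(c), blob_radius, 1.0))
    return AxonTruth(
        centerlines=centerlines,
        radii=[radius] * n_tubes,
        brightness=[brightness] * n_tubes,
        blobs=blobs,
    )


def _stamp_gaussian(vol: np.ndarray, center: np.ndarray, radius: float, peak: float) -> None:
    """max-combine an isotropic Gaussian bump into the volume."""
    w = int(np.ceil(3 * radius))
    c0 = np.round(center).astype(int)
    lo = np.maximum(c0 - w, 0)
    hi = np.minimum(c0 + w + 1, vol.shape)
    if np.any(lo >= hi):
        return
    ax = [np.arange(lo[i], hi[i], dtype=float) - center[i] for i in range(3)]
    d2 = (
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    bump = peak * np.exp(-d2 / (2.0 * radius * radius))
    block = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(block, bump, out=block)


def simulate_axon_probability(
    truth: AxonTruth,
    shape: tuple[int, int, int],
    noise_sd: float = 0.0,
    seed: int = 0,
    voxel_size_um: tuple[float, float, float] = DEFAULT_NATIVE_VOXEL_UM,
) -> ProbabilityVolume:
    """Render a phantom probability volume from ground truth.

    Tubes have Gaussian cross-sections (max-combined so overlaps do not
    exceed the brightness), blobs are bright Gaussian spheres, and additive
    Gaussian noise is clipped to [0, 1].  Deterministic for a fixed seed.
    """
    vol = np.zeros(shape, dtype=float)
    for line, radius, bright in zip(truth.centerlines, truth.radii, truth.brightness):
        line = np.asarray(line, dtype=float)
        if np.any(line < 0) or np.any(line >= np.asarray(shape)):
            raise ValueError("centerline leaves the volume")
        if len(line) == 1:
            samples = line
        else:
            seglen = np.linalg.norm(np.diff(line, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seglen)])
            s = np.arange(0.0, cum[-1] + 1e-9, 0.5)
            samples = np.stack([np.interp(s, cum, line[:, i]) for i in range(3)], axis=1)
        for p in samples:
            _stamp_gaussian(vol, p, radius, bright)
    for center, radius, bright in truth.blobs:
        _stamp_gaussian(vol, np.asarray(center, dtype=float), radius, bright)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=shape)
    np.clip(vol, 0.0, 1.0, out=vol)
    return ProbabilityVolume(values=vol, voxel_size_um=voxel_size_um)


# ====================================================================== #
# injection cohorts


@dataclass(frozen=True)
class TopographySpec:
    """Generating parameters of the anatomical mirror map.

    Hotspot centers obey ``AP = intercept + slope·|ML| + ε`` with
    ``ε ~ N(0, ap_noise_sd_mm²)``.  The slope default of 0.5 mm AP per mm
    |ML| sits in the middle of the range reported for cortical projection
    classes; injections span the barrel field and the supplemental
    somatosensory area.
    """

    intercept_ap_mm: float = 0.25
    slope: float = 0.5
    sigma_spot_px: float = 6.0
    ap_noise_sd_mm: float = 0.1
    ml_positions_mm: tuple[float, ...] = (2.6, 2.9, 3.2, 3.5, 3.8, 4.05, 4.3)
    cells_range: tuple[int, int] = (80, 150)
    axon_voxels_per_cell: float = 50.0
    hotspot_ml_mm: float = 1.3
    cp_fraction: float = 0.2
    cp_sigma_px: float = 8.0
    injection_side: str = "left"

    def __post_init__(self) -> None:
        if self.sigma_spot_px <= 0:
            raise ValueError("sigma_spot_px must be > 0")
        if self.ap_noise_sd_mm < 0:
            raise ValueError("ap_noise_sd_mm must be >= 0")
        if self.injection_side not in ("left", "right"):
            raise ValueError("injection_side must be 'left' or 'right'")
        if not 0.0 <= self.cp_fraction < 1.0:
            raise ValueError("cp_fraction must be in [0, 1)")
        if self.cells_range[0] < 1 or self.cells_range[1] < self.cells_range[0]:
            raise ValueError(f"invalid cells_range {self.cells_range}")


@dataclass
class SampleTruth:
    """Everything the generator drew for one synthetic injection."""

    sample_id: str
    ml_abs_mm: float
    hotspot_ap_mm: float
    ap_noise_mm: float
    n_cells: int
    budget: int
    budget_mo: int
    budget_cp: int
    injection_center_voxel: tuple[float, float, float]
    injection_region: str
    centerlines: list[np.ndarray] | None = None


@dataclass
class CohortTruth:
    spec: TopographySpec
    samples: list[SampleTruth]


@dataclass
class SyntheticSample:
    """One synthetic injection: inputs plus per-sample metadata.

    In ``atlas`` mode the sample carries a ready 25 µm density map; in
    ``native`` mode it carries a native-resolution probability volume and
    the (known) native→atlas transform, so the skeletonization and mapping
    stages run for real.
    """

    sample_id: str
    cre_line: str
    injection_side: str
    n_cells: int
    injection_mask: np.ndarray
    truth: SampleTruth
    density: DensityMap | None = None
    probability: ProbabilityVolume | None = None
    transform: TransformChain | None = None


def _rejection_sample(
    rng: np.random.Generator,
    n: int,
    draw: "callable",
    accept: "callable",
    max_iter: int = 80,
) -> np.ndarray:
    """Draw voxel coordinates until ``n`` pass the acceptance predicate."""
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_iter):
        if got >= n:
            break
        batch = draw(max(2 * (n - got), 64))
        ok = accept(batch)
        kept = batch[ok]
        out.append(kept)
        got += len(kept)
    if got < n:
        raise RuntimeError("rejection sampling failed; hotspot is outside its target region")
    return np.concatenate(out)[:n]


def simulate_injection_cohort(
    topo: TopographySpec | None = None,
    atlas: tuple[AnnotationVolume, StructureGraph, CoordinateFrame] | None = None,
    n_samples: int | None = None,
    seed: int = 0,
    mode: str = "atlas",
    cre_line: str = "SynthCre",
    native_shape: tuple[int, int, int] = (120, 96, 120),
    native_voxel_size_um: tuple[float, float, float] = DEFAULT_NATIVE_VOXEL_UM,
) -> tuple[list[SyntheticSample], pd.DataFrame, CohortTruth]:
    """Generate an injection cohort obeying the mirror map.

    Each sample gets an injection mask inside SSp-bfd or SSs (by its |ML|
    position), a labeled-cell count, and axon counts concentrated in a
    Gaussian motor-cortex hotspot (layers 2/3 and 5 of MOp/MOs) centered at
    ``AP = a + s·|ML| + ε``, plus a caudoputamen deposit.  The axon-voxel
    budget scales with the cell count, and the deposited counts satisfy
    ``density total × n_cells = budget`` exactly (the generator's
    bookkeeping invariant).  ``native`` mode instead renders tube phantoms
    in a native-resolution window over the hotspot, with the exact affine
    into atlas space, exercising skeletonization and mapping end-to-end.
    """
    topo = topo or TopographySpec()
    if atlas is None:
        atlas = make_toy_atlas()
    annotation, graph, frame = atlas
    if mode not in ("atlas", "native"):
        raise ValueError(f"mode must be 'atlas' or 'native', got {mode!r}")
    if n_samples is None:
        n_samples = len(topo.ml_positions_mm)
    if n_samples < 2:
        raise ValueError("cohort needs at least 2 samples (downstream regression needs >= 3)")
    if n_samples == 2:
        warnings.warn("2-sample cohort: downstream regression requires >= 3 points", stacklevel=2)
    if n_samples > len(topo.ml_positions_mm):
        raise ValueError(
            f"n_samples={n_samples} exceeds the {len(topo.ml_positions_mm)} configured positions"
        )

    rng = np.random.default_rng(seed)
    sign = -1.0 if topo.injection_side == "left" else 1.0

    mo_ids = np.array(sorted(
        set().union(*(graph.self_and_descendants(graph.id_of(f"{r}{l}"))
                      for r in ("MOp", "MOs") for l in ("2/3", "5")))
    ))
    cp_ids = np.array(sorted(graph.self_and_descendants(graph.id_of("CP"))))

    samples: list[SyntheticSample] = []
    truths: list[SampleTruth] = []
    meta_rows: list[dict] = []

    for i in range(n_samples):
        ml = float(topo.ml_positions_mm[i])
        sid = f"sample{i:02d}"
        n_cells = int(rng.integers(topo.cells_range[0], topo.cells_range[1] + 1))
        budget = int(round(n_cells * topo.axon_voxels_per_cell))
        n_cp = int(round(budget * topo.cp_fraction))
        n_mo = budget - n_cp
        eps = float(rng.normal(0.0, topo.ap_noise_sd_mm)) if topo.ap_noise_sd_mm > 0 else 0.0
        ap_c = topo.intercept_ap_mm + topo.slope * ml + eps

        center_vox = frame.bregma_mm_to_voxel([ap_c, 0.0, sign * topo.hotspot_ml_mm])
        cp_center = frame.bregma_mm_to_voxel([0.5, 1.7, sign * 2.0])
        # DV support of the target layers (2/3 and 5): 0.1–0.7 mm below surface
        dv_lo = frame.bregma_voxel[DV] + 0.1 * 1000.0 / frame.voxel_size_um
        dv_hi = frame.bregma_voxel[DV] + 0.7 * 1000.0 / frame.voxel_size_um

        def draw_mo(m: int) -> np.ndarray:
            pts = np.empty((m, 3))
            pts[:, AP] = rng.normal(center_vox[AP], topo.sigma_spot_px, m)
            pts[:, DV] = rng.uniform(dv_lo, dv_hi, m)
            pts[:, ML] = rng.normal(center_vox[ML], topo.sigma_spot_px, m)
            return np.floor(pts + 0.5).astype(np.int64)

        def draw_cp(m: int) -> np.ndarray:
            pts = rng.normal(cp_center, topo.cp_sigma_px, (m, 3))
            return np.floor(pts + 0.5).astype(np.int64)

        def in_ids(pts: np.ndarray, ids: np.ndarray) -> np.ndarray:
            shape = np.asarray(annotation.shape)
            ok = np.all((pts >= 0) & (pts < shape), axis=1)
            res = np.zeros(len(pts), dtype=bool)
            if ok.any():
                vals = annotation.id_grid[tuple(pts[ok].T)]
                res[ok] = np.isin(vals, ids)
            return res

        mo_pts = _rejection_sample(rng, n_mo, draw_mo, lambda p: in_ids(p, mo_ids))
        cp_pts = (
            _rejection_sample(rng, n_cp, draw_cp, lambda p: in_ids(p, cp_ids))
            if n_cp
            else np.empty((0, 3), dtype=np.int64)
        )
        all_pts = np.concatenate([mo_pts, cp_pts])

        # injection mask: 0.3 mm cube centered in the somatosensory band
        inj_center = frame.bregma_mm_to_voxel([-1.5, 0.3, sign * ml])
        half = int(round(0.15 * 1000.0 / frame.voxel_size_um))
        mask = np.zeros(annotation.shape, dtype=bool)
        c = np.round(inj_center).astype(int)
        mask[
            c[AP] - half : c[AP] + half,
            max(0, c[DV] - half) : c[DV] + half,
            c[ML] - half : c[ML] + half,
        ] = True
        center_id = int(annotation.id_grid[c[AP], c[DV], c[ML]])
        if center_id == 0:
            inj_region = "unassigned"
        else:
            parent = graph.parent(center_id)
            inj_region = graph.acronym(parent if parent is not None else center_id)

        truth = SampleTruth(
            sample_id=sid,
            ml_abs_mm=ml,
            hotspot_ap_mm=ap_c,
            ap_noise_mm=eps,
            n_cells=n_cells,
            budget=budget,
            budget_mo=n_mo,
            budget_cp=n_cp,
            injection_center_voxel=tuple(float(x) for x in inj_center),
            injection_region=inj_region,
        )

        if mode == "atlas":
            # accumulate straight into float64 (one pass, no integer copy)
            grid = np.zeros(annotation.shape, dtype=np.float64)
            np.add.at(grid, tuple(all_pts.T), 1.0)
            grid /= n_cells
            dmap = DensityMap(
                grid=grid,
                n_cells=n_cells,
                voxel_size_um=annotation.voxel_size_um,
                meta={
                    "sample_id": sid,
                    "cre_line": cre_line,
                    "injection_region": inj_region,
                    "injection_side": topo.injection_side,
                    "counts_total": int(len(all_pts)),
                    "out_of_bounds_count": 0,
                },
            )
            sample = SyntheticSample(
                sample_id=sid, cre_line=cre_line, injection_side=topo.injection_side,
                n_cells=n_cells, injection_mask=mask, truth=truth, density=dmap,
            )
        else:
            nat_vox = np.asarray(native_voxel_size_um, dtype=float)
            window_um = np.asarray(native_shape) * nat_vox
            center_um = np.asarray(center_vox) * frame.voxel_size_um
            origin_um = center_um - window_um / 2.0
            # DV: keep the window inside the cortical depth (start at surface)
            origin_um[DV] = max(0.0, origin_um[DV])
            chain = TransformChain([Affine.translation(origin_um)])
            center_native = (center_um - origin_um) / nat_vox
            spread_native = topo.sigma_spot_px * frame.voxel_size_um / nat_vox
            starts = center_native + rng.normal(0.0, 1.0, (3, 3)) * spread_native
            starts = np.clip(starts, 6, np.asarray(native_shape) - 7)
            tube_truth = make_tube_truth(
                native_shape, n_tubes=3, n_steps=200, radius=1.0,
                seed=int(rng.integers(2**31)), margin=5, n_blobs=2,
                start_points=starts,
            )
            prob = simulate_axon_probability(
                tube_truth, native_shape, noise_sd=0.02,
                seed=int(rng.integers(2**31)), voxel_size_um=native_voxel_size_um,
            )
            truth.centerlines = tube_truth.centerlines
            sample = SyntheticSample(
                sample_id=sid, cre_line=cre_line, injection_side=topo.injection_side,
                n_cells=n_cells, injection_mask=mask, truth=truth,
                probability=prob, transform=chain,
            )

        samples.append(sample)
        truths.append(truth)
        meta_rows.append(
            {
                "sample_id": sid,
                "cre_line": cre_line,
                "injection_side": topo.injection_side,
                "injection_ml_mm": sign * ml,
                "injection_ap_mm": -1.5,
                "n_cells": n_cells,
                "injection_region": inj_region,
            }
        )

    metadata = pd.DataFrame(meta_rows)
    return samples, metadata, CohortTruth(spec=topo, samples=truths)


# ====================================================================== #
# wide-field sessions


@dataclass(frozen=True)
class WidefieldTruth:
    """Generating parameters of a wide-field optogenetic session.

    The response center follows the functional mirror map
    ``AP = intercept + slope·|ML_stim|`` at a fixed frontal ML; responses
    are separable (Gaussian in space, boxcar in time).  Frame geometry
    emulates the post-binned camera: 160 × 128 pixels at 62.5 µm.  Centers
    are snapped to the pixel lattice so the evoked-map peak equals the
    amplitude exactly in the noise-free limit.
    """

    stim_points_mm: tuple[tuple[float, float], ...] = (
        (2.5, -1.5), (3.0, -1.5), (3.5, -1.5), (4.0, -1.5),
    )  # (ML, AP) of each stimulation site; 0.5 mm grid spacing
    slope: float = 0.5
    intercept_ap_mm: float = 0.25
    response_ml_mm: float = 1.3
    amplitude: float = 0.05
    sigma_px: float = 4.0
    onset_ms: float = 0.0
    duration_ms: float = 500.0
    noise_sd: float = 0.01
    trials_per_point: int = 10
    frame_shape: tuple[int, int] = (160, 128)
    pixel_size_um: float = 62.5
    bregma_pixel: tuple[float, float] = (48.0, 64.0)
    timing: str = "fine"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.trials_per_point < 1:
            raise ValueError("trials_per_point must be >= 1")
        if self.timing not in ("fine", "coarse"):
            raise ValueError("timing must be 'fine' or 'coarse'")

    @classmethod
    def from_topography(cls, topo: TopographySpec, **overrides) -> "WidefieldTruth":
        """Share the anatomical mirror map's slope/intercept and hotspot ML."""
        return cls(
            slope=topo.slope,
            intercept_ap_mm=topo.intercept_ap_mm,
            response_ml_mm=topo.hotspot_ml_mm,
            **overrides,
        )

    def frontal_mask_origin(self, mask_shape: tuple[int, int] = (25, 40)) -> tuple[int, int]:
        """Top-left corner of a frontal mask covering every response center."""
        px_per_mm = 1000.0 / self.pixel_size_um
        ap_max = self.intercept_ap_mm + self.slope * max(abs(m) for m, _ in self.stim_points_mm)
        rc_min = int(round(self.bregma_pixel[0] - ap_max * px_per_mm))
        cc = int(round(self.bregma_pixel[1] + self.response_ml_mm * px_per_mm))
        return max(0, rc_min - 5), max(0, cc - mask_shape[1] // 2)

    def frame_times_ms(self) -> np.ndarray:
        """Irregular acquisition clock: 100 Hz peri-stimulus, 50 Hz during.

        ``coarse`` timing subsamples both epochs for cheap simulations
        while preserving the timestamp-selection semantics.
        """
        if self.timing == "fine":
            return np.concatenate(
                [np.arange(-300.0, 0.0, 10.0), np.arange(10.0, 500.0, 20.0),
                 np.arange(500.0, 710.0, 10.0)]
            )
        return np.concatenate([np.arange(-300.0, 0.0, 50.0), np.arange(10.0, 261.0, 50.0)])


@dataclass
class SessionTruth:
    """Per-session ground truth: snapped response centers per grid point."""

    truth: WidefieldTruth
    centers_mm: dict[int, tuple[float, float]]
    centers_px: dict[int, tuple[int, int]]


def simulate_widefield_session(
    truth: WidefieldTruth | None = None,
    seed: int = 0,
    mouse_id: str = "mouse0",
    cre_line: str = "SynthCre",
) -> tuple[WidefieldSession, SessionTruth]:
    """Simulate one mouse's stimulation session.

    Per-trial movies are ``F0 · (1 + response) + F0 · noise`` with the
    response a spatial Gaussian gated by a boxcar over the stimulation
    epoch; the stimulation log records each trial's grid point.
    Deterministic for a fixed seed.
    """
    truth = truth or WidefieldTruth()
    rng = np.random.default_rng(seed)
    h, w = truth.frame_shape
    times = truth.frame_times_ms()
    px_per_mm = 1000.0 / truth.pixel_size_um

    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    f0 = 100.0 + 10.0 * rows[:, None] / h + 5.0 * cols[None, :] / w

    templates = []
    centers_mm: dict[int, tuple[float, float]] = {}
    centers_px: dict[int, tuple[int, int]] = {}
    for gp, (ml_stim, _ap_stim) in enumerate(truth.stim_points_mm):
        ap_c = truth.intercept_ap_mm + truth.slope * abs(ml_stim)
        rc = int(round(truth.bregma_pixel[0] - ap_c * px_per_mm))
        cc = int(round(truth.bregma_pixel[1] + truth.response_ml_mm * px_per_mm))
        if not (0 <= rc < h and 0 <= cc < w):
            raise ValueError(f"response center for grid point {gp} falls outside the frame")
        g = np.exp(
            -(((rows[:, None] - rc) ** 2) + ((cols[None, :] - cc) ** 2))
            / (2.0 * truth.sigma_px**2)
        )
        templates.append(truth.amplitude * g)
        centers_px[gp] = (rc, cc)
        centers_mm[gp] = (
            (truth.bregma_pixel[0] - rc) / px_per_mm,
            (cc - truth.bregma_pixel[1]) / px_per_mm,
        )
    templates = np.stack(templates)

    point_ids = np.repeat(np.arange(len(truth.stim_points_mm)), truth.trials_per_point)
    rng.shuffle(point_ids)
    n_trials = len(point_ids)

    gate = ((times >= truth.onset_ms) & (times < truth.onset_ms + truth.duration_ms)).astype(float)
    response = templates[point_ids][:, None] * gate[None, :, None, None]
    movie = (f0[None, None] * (1.0 + response)).astype(np.float32)
    if truth.noise_sd > 0:
        noise = rng.standard_normal(movie.shape, dtype=np.float32) * np.float32(truth.noise_sd)
        movie = movie + f0[None, None].astype(np.float32) * noise

    stim_log = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "grid_point_id": point_ids,
            "stim_ml_mm": [truth.stim_points_mm[g][0] for g in point_ids],
            "stim_ap_mm": [truth.stim_points_mm[g][1] for g in point_ids],
        }
    )
    session = WidefieldSession(
        movie=movie,
        frame_times_ms=times,
        stim_log=stim_log,
        pixel_size_um=truth.pixel_size_um,
        bregma_pixel=truth.bregma_pixel,
        mouse_id=mouse_id,
        cre_line=cre_line,
    )
    return session, SessionTruth(truth=truth, centers_mm=centers_mm, centers_px=centers_px)
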