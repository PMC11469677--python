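"""End-to-end pipeline driver over a file bundle.

A *bundle* is a directory of the pipeline's inputs in the formats the
readers understand: the atlas (annotation TIFF + sidecar, structure-graph
JSON), per-sample native probability volumes with their native→atlas
transforms and injection masks, and a ``samples.csv`` metadata table.
``write_synthetic_bundle`` produces one from the generators;
``run_pipeline`` executes skeletonize → map → quantify → correlate →
topography on it, writing tabular outputs and a manifest (input hashes,
parameters, package version, seed) sufficient to re-execute the run.
Reruns from the same manifest are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import AnnotationVolume, CoordinateFrame, StructureGraph, load_structure_graph
from .config import PipelineConfig
from .density import (
    TransformChain,
    bin_to_atlas,
    injection_qc,
    normalize_per_cell,
    transform_coords,
)
from .io import read_volume, write_volume
from .regions import quantify_by_region, rank_regions, rollup_layers
from .similarity import categorical_correlation, order_samples, spatial_correlation
from .skeleton import (
    ProbabilityVolume,
    filter_components,
    skeleton_to_coords,
    weighted_skeleton,
    write_coords,
)
from .synthetic import TopographySpec, make_toy_atlas, simulate_injection_cohort
from .topography import fit_topography, hotspot_metrics, mo_axon_map

__all__ = [
    "write_synthetic_bundle",
    "load_bundle_atlas",
    "run_pipeline",
    "run_from_manifest",
]


def _stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out per stage by stable hashing of the name."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------- #


def write_synthetic_bundle(
    out_dir: str | Path,
    topo: TopographySpec | None = None,
    n_samples: int | None = None,
    seed: int = 0,
    native_shape: tuple[int, int, int] = (120, 96, 120),
) -> Path:
    """Generate a native-mode synthetic cohort and write it as a bundle."""
    out = Path(out_dir)
    (out / "atlas").mkdir(parents=True, exist_ok=True)
    annotation, graph, frame = make_toy_atlas()
    geometry = {
        "voxel_size_um": annotation.voxel_size_um,
        "bregma_voxel": list(frame.bregma_voxel),
        "midline_ml": frame.midline_ml,
    }
    write_volume(annotation.id_grid, out / "atlas" / "annotation.tif", geometry)
    graph.to_json(out / "atlas" / "structure_graph.json")

    samples, metadata, truth = simulate_injection_cohort(
        topo=topo,
        atlas=(annotation, graph, frame),
        n_samples=n_samples,
        seed=_stage_seed(seed, "simulate"),
        mode="native",
        native_shape=native_shape,
    )
    for s in samples:
        sdir = out / "samples" / s.sample_id
        sdir.mkdir(parents=True, exist_ok=True)
        assert s.probability is not None and s.transform is not None
        write_volume(
            s.probability.values.astype(np.float32),
            sdir / "probability.tif",
            {"voxel_size_um": list(s.probability.voxel_size_um)},
        )
        s.transform.to_json(sdir / "transform.json")
        write_volume(
            s.injection_mask.astype(np.uint8),
            sdir / "injection_mask.tif",
            {"voxel_size_um": annotation.voxel_size_um},
        )
    metadata.to_csv(out / "samples.csv", index=False)
    return out


def load_bundle_atlas(
    bundle: Path,
) -> tuple[AnnotationVolume, StructureGraph, CoordinateFrame]:
    grid, meta = read_volume(bundle / "atlas" / "annotation.tif")
    annotation = AnnotationVolume(grid, float(meta["voxel_size_um"]))
    graph = load_structure_graph(bundle / "atlas" / "structure_graph.json")
    frame = CoordinateFrame(
        bregma_voxel=tuple(meta["bregma_voxel"]),
        midline_ml=float(meta["midline_ml"]),
        voxel_size_um=float(meta["voxel_size_um"]),
    )
    return annotation, graph, frame


# ---------------------------------------------------------------------- #


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the axonal pipeline on a bundle; return an artifact summary.

    Stages per sample: weighted skeletonization, component filtering,
    coordinate export, transform + binning into atlas space, per-cell
    normalization, injection QC.  Cohort stages: region tables with layer
    rollup, top-N ranking over the group average, categorical and spatial
    correlation matrices, motor-cortex hotspot metrics and the
    injection-vs-hotspot regression.  Every output is a CSV/JSON file under
    ``config.output_dir`` plus a ``manifest.json``.
    """
    if not config.input_dir or not config.output_dir:
        raise ValueError("config must set input_dir and output_dir")
    bundle = Path(config.input_dir)
    if not bundle.exists():
        raise ValueError(f"input bundle {bundle} does not exist")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation, graph, frame = load_bundle_atlas(bundle)
    metadata = pd.read_csv(bundle / "samples.csv")

    input_hashes = {
        str(p.relative_to(bundle)): _sha256(p)
        for p in sorted(bundle.rglob("*"))
        if p.is_file()
    }

    density_maps = {}
    tables = {}
    qc_rows = []
    hotspot_rows = []
    conservation = []

    for row in metadata.itertuples():
        sid = row.sample_id
        sdir = bundle / "samples" / sid
        try:
            prob_grid, prob_meta = read_volume(sdir / "probability.tif")
            prob = ProbabilityVolume(
                values=prob_grid.astype(float),
                voxel_size_um=tuple(prob_meta["voxel_size_um"]),
            )
            chain = TransformChain.from_json(sdir / "transform.json")
            mask_grid, _ = read_volume(sdir / "injection_mask.tif")

            skel = weighted_skeleton(prob, thresholds=config.thresholds)
            skel, report = filter_components(
                skel, min_size=config.min_component_size, connectivity=config.connectivity
            )
            coords = skeleton_to_coords(skel)
            sample_out = out / "samples" / sid
            sample_out.mkdir(parents=True, exist_ok=True)
            write_coords(coords, sample_out / "skeleton_coords.csv")
            report.to_csv(sample_out / "component_report.csv", index=False)

            atlas_coords, tinfo = transform_coords(
                coords, chain, prob.voxel_size_um, config.atlas_voxel_size_um
            )
            counts = bin_to_atlas(atlas_coords, annotation)
            if counts.total + counts.out_of_bounds_count != skel.n_voxels:
                raise AssertionError(f"count conservation violated for {sid}")
            conservation.append(
                {
                    "sample_id": sid,
                    "skeleton_voxels": skel.n_voxels,
                    "binned": counts.total,
                    "out_of_bounds": counts.out_of_bounds_count,
                    "out_of_support": tinfo["out_of_support"],
                }
            )
            dmap = normalize_per_cell(
                counts,
                int(row.n_cells),
                meta={
                    "sample_id": sid,
                    "cre_line": row.cre_line,
                    "injection_side": row.injection_side,
                },
            )

            qc = injection_qc(
                mask_grid.astype(bool), annotation, graph,
                target_acronyms=config.qc_targets, min_fraction=config.qc_min_fraction,
            )
            dmap.meta["included"] = qc.included
            density_maps[sid] = dmap
            qc_rows.append(
                {
                    "sample_id": sid,
                    "fraction_in_targets": qc.fraction_in_targets,
                    "included": qc.included,
                    "volume_mm3": qc.volume_mm3,
                    "center_ap": qc.center_voxel[0],
                    "center_dv": qc.center_voxel[1],
                    "center_ml": qc.center_voxel[2],
                }
            )

            table = quantify_by_region(dmap, annotation, graph, frame, row.injection_side)
            tables[sid] = table
            table.to_csv(sample_out / "region_table.csv", index=False)

            map2d = mo_axon_map(
                dmap, annotation, graph, regions=config.mo_regions, layers=config.mo_layers
            )
            hs = hotspot_metrics(
                map2d, frame=frame,
                pixel_size_um=annotation.voxel_size_um,
                sigma_px=config.sigma_hotspot_px,
                levels=config.contour_levels,
                roi_um=config.roi_um,
            )
            inj_mm = frame.voxel_to_bregma_mm(qc.center_voxel)
            hotspot_rows.append(
                {
                    "sample_id": sid,
                    "included": qc.included,
                    "hotspot_defined": hs.defined,
                    "injection_abs_ml_mm": abs(float(inj_mm[2])),
                    "centroid95_ap_mm": hs.centroid95_mm[0],
                    "centroid95_ml_mm": hs.centroid95_mm[1],
                    "area75_mm2": hs.area75_mm2,
                    "peak_roi_density_per_mm2": hs.peak_roi_density,
                }
            )
        except Exception as err:  # noqa: BLE001 - abort with stage context
            (out / "FAILED").write_text(f"sample {sid}: {err}\n")
            raise RuntimeError(f"pipeline failed at sample {sid}: {err}") from err

    pd.DataFrame(qc_rows).to_csv(out / "injection_qc.csv", index=False)
    pd.DataFrame(conservation).to_csv(out / "count_conservation.csv", index=False)

    included_ids = [r["sample_id"] for r in qc_rows if r["included"]]
    rolled = {
        sid: rollup_layers(tables[sid], graph, levels=config.rollup_levels) for sid in tables
    }
    ranking = rank_regions([rolled[sid] for sid in included_ids] or list(rolled.values()),
                           top_n=config.top_n)
    ranking.to_csv(out / "region_ranking.csv", index=False)

    order = order_samples(metadata, line_order=config.line_order)
    cat = categorical_correlation(tables, order)
    cat.to_csv(out / "correlation_categorical.csv")
    spat = spatial_correlation(density_maps, order, sigma_voxels=config.sigma_spatial)
    spat.to_csv(out / "correlation_spatial.csv")

    hotspots = pd.DataFrame(hotspot_rows)
    hotspots.to_csv(out / "hotspots.csv", index=False)
    usable = hotspots[hotspots["included"] & hotspots["hotspot_defined"]]
    fit_payload: dict = {"n": int(len(usable))}
    if len(usable) >= 3:
        fit = fit_topography(
            list(zip(usable["injection_abs_ml_mm"], usable["centroid95_ap_mm"]))
        )
        fit_payload = asdict(fit)
    (out / "topography_fit.json").write_text(json.dumps(fit_payload, indent=1, sort_keys=True))

    manifest = {
        "config": config.to_dict(),
        "inputs": input_hashes,
        "version": __version__,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "n_samples": len(metadata),
        "n_included": len(included_ids),
        "topography_fit": fit_payload,
        "output_dir": str(out),
    }


def run_from_manifest(manifest_path: str | Path, output_dir: str | Path) -> dict:
    """Re-execute a run from its manifest alone (into a fresh directory)."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = PipelineConfig.from_dict(manifest["config"])
    config.output_dir = str(output_dir)
    return run_pipeline(config)
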