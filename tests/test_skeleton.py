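"""Weighted skeletonization, component filtering and curation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as sk_skeletonize

from projquant.skeleton import (
    AxonSkeleton,
    CurationDecision,
    DEFAULT_THRESHOLDS,
    ProbabilityVolume,
    apply_curation,
    filter_components,
    read_coords,
    skeleton_to_coords,
    weighted_skeleton,
    write_coords,
)
from projquant.synthetic import make_tube_truth, simulate_axon_probability

SUBSET_SUMS = {
    round(sum(c), 10)
    for m in range(1, len(DEFAULT_THRESHOLDS) + 1)
    for c in itertools.combinations(DEFAULT_THRESHOLDS, m)
}


def brute_force_weighted_skeleton(values: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Independent accumulation: binarize → thin → scale → add, per threshold."""
    acc = np.zeros(values.shape, dtype=float)
    for t in thresholds:
        mask = values >= t
        if mask.any():
            acc = acc + t * sk_skeletonize(mask).astype(float)
    return acc


def skeleton_from_voxels(voxel_blocks: list[np.ndarray], shape) -> AxonSkeleton:
    """Assemble a labeled skeleton from explicit voxel coordinate blocks."""
    coords = np.concatenate(voxel_blocks)
    labels = np.concatenate(
        [np.full(len(b), i + 1, dtype=np.int64) for i, b in enumerate(voxel_blocks)]
    )
    sizes = {i + 1: len(b) for i, b in enumerate(voxel_blocks)}
    return AxonSkeleton(
        coords=coords,
        weights=np.full(len(coords), 0.2),
        component_ids=labels,
        component_sizes=sizes,
        shape=shape,
    )


class TestWeightedSkeleton:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_accumulation_on_phantoms(self, seed):
        shape = (50, 50, 50)
        truth = make_tube_truth(shape, n_tubes=2, n_steps=60, seed=seed, n_blobs=1)
        prob = simulate_axon_probability(truth, shape, noise_sd=0.05, seed=seed)
        skel = weighted_skeleton(prob)
        oracle = brute_force_weighted_skeleton(prob.values)
        assert np.allclose(skel.to_dense_weights(), oracle)

    def test_weights_are_threshold_subset_sums_bounded_by_4_4(self, small_phantom):
        prob, _ = small_phantom
        skel = weighted_skeleton(prob)
        assert skel.weights.max() <= 4.4 + 1e-12
        assert {round(float(w), 10) for w in skel.weights} <= SUBSET_SUMS

    def test_saturated_voxel_gets_full_weight(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 2:7, 4] = 1.0  # a short bar above every threshold
        skel = weighted_skeleton(ProbabilityVolume(vals))
        assert skel.weights.max() == pytest.approx(sum(DEFAULT_THRESHOLDS))  # 4.4

    def test_all_zero_volume_yields_empty_skeleton(self):
        skel = weighted_skeleton(ProbabilityVolume(np.zeros((10, 10, 10))))
        assert skel.n_voxels == 0
        assert skel.component_sizes == {}

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.5, 0.4), (0.5, 1.0)])
    def test_invalid_thresholds_rejected(self, bad):
        with pytest.raises(ValueError):
            weighted_skeleton(ProbabilityVolume(np.zeros((5, 5, 5))), thresholds=bad)

    def test_skeleton_tracks_true_centerline(self):
        """≥95% of noise-free single-tube skeleton voxels lie within 1 voxel
        of the generating centerline."""
        shape = (60, 60, 60)
        truth = make_tube_truth(shape, n_tubes=1, n_steps=100, seed=7)
        prob = simulate_axon_probability(truth, shape, noise_sd=0.0)
        skel = weighted_skeleton(prob)
        line = truth.centerlines[0]
        seglen = np.linalg.norm(np.diff(line, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        dense = np.stack(
            [np.interp(np.arange(0, cum[-1], 0.1), cum, line[:, i]) for i in range(3)], axis=1
        )
        dist, _ = cKDTree(dense).query(skel.coords)
        assert np.mean(dist <= 1.0) >= 0.95


class TestFilterComponents:
    def test_strictly_less_than_cutoff_boundary(self, rng):
        # 9,999 voxels is removed, 10,000 survives: the rule is strictly "<"
        big = np.stack(np.unravel_index(np.arange(10_000), (100, 10, 10)), axis=1)
        small = np.stack(np.unravel_index(np.arange(9_999), (100, 10, 10)), axis=1)
        small = small + np.array([0, 0, 50])
        skel = skeleton_from_voxels([big, small], shape=(100, 10, 60))
        out, report = filter_components(skel, min_size=10_000)
        assert len(out.component_sizes) == 1
        assert out.n_voxels == 10_000
        assert len(report) == 2
        assert report.set_index("size")["kept"].to_dict() == {10_000: True, 9_999: False}

    def test_empty_skeleton_passes_through(self):
        skel = AxonSkeleton(
            coords=np.empty((0, 3)), weights=[], component_ids=[], component_sizes={},
            shape=(5, 5, 5),
        )
        out, report = filter_components(skel, min_size=10)
        assert out.n_voxels == 0 and len(report) == 0

    def test_idempotent(self, small_phantom):
        prob, _ = small_phantom
        skel = weighted_skeleton(prob)
        once, _ = filter_components(skel, min_size=30)
        twice, _ = filter_components(once, min_size=30)
        assert np.array_equal(once.coords, twice.coords)
        assert np.array_equal(once.component_ids, twice.component_ids)
        assert once.component_sizes == twice.component_sizes

    def test_relabels_by_descending_size(self):
        a = np.array([[i, 0, 0] for i in range(3)])
        b = np.array([[i, 2, 0] for i in range(7)])
        skel = skeleton_from_voxels([a, b], shape=(10, 5, 5))
        out, _ = filter_components(skel, min_size=1)
        assert out.component_sizes == {1: 7, 2: 3}

    def test_phantom_tube_survives_blob_removed(self):
        tube = np.stack([np.arange(40), np.full(40, 5), np.full(40, 5)], axis=1)
        blob = np.array([[45, 20, 20], [45, 20, 21], [45, 21, 20]])
        skel = skeleton_from_voxels([tube, blob], shape=(50, 30, 30))
        out, report = filter_components(skel, min_size=10)
        assert len(out.component_sizes) == 1
        assert len(report) == 2


class TestCuration:
    def _skel(self):
        a = np.array([[i, 0, 0] for i in range(5)])
        b = np.array([[i, 3, 3] for i in range(3)])
        return skeleton_from_voxels([a, b], shape=(10, 5, 5))

    def test_all_keep_is_identity(self):
        skel = self._skel()
        out = apply_curation(skel, CurationDecision({1: "keep", 2: "keep"}))
        assert np.array_equal(out.coords, skel.coords)
        assert out.component_sizes == skel.component_sizes

    def test_drop_removes_exactly_that_component(self):
        skel = self._skel()
        out = apply_curation(skel, CurationDecision({2: "drop"}, reasons={2: "edge artifact"}))
        assert out.n_voxels == skel.n_voxels - skel.component_sizes[2]
        assert 2 not in out.component_sizes
        assert out.provenance["curation"]["reasons"][2] == "edge artifact"

    def test_unknown_label_is_an_error(self):
        with pytest.raises(KeyError, match="99"):
            apply_curation(self._skel(), CurationDecision({99: "drop"}))

    def test_invalid_verdict_rejected(self):
        with pytest.raises(ValueError, match="keep|drop"):
            CurationDecision({1: "maybe"})


class TestCoordinateList:
    def test_one_row_per_voxel_sorted_unique(self, small_phantom):
        prob, _ = small_phantom
        skel = weighted_skeleton(prob)
        coords = skeleton_to_coords(skel)
        assert len(coords) == skel.n_voxels
        arr = coords[["ap", "dv", "ml"]].to_numpy()
        assert len(np.unique(arr, axis=0)) == len(arr)
        assert np.array_equal(arr, arr[np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0]))])

    def test_csv_round_trip(self, small_phantom, tmp_path):
        prob, _ = small_phantom
        coords = skeleton_to_coords(weighted_skeleton(prob))
        path = tmp_path / "coords.csv"
        write_coords(coords, path)
        again = read_coords(path)
        pd.testing.assert_frame_equal(coords.reset_index(drop=True), again)
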