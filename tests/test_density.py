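"""Coordinate transforms, atlas binning, normalization, QC and projections."""

import numpy as np
import pytest

from projquant.atlas import AnnotationVolume
from projquant.density import (
    Affine,
    CountsVolume,
    DensityMap,
    DisplacementField,
    TransformChain,
    bin_to_atlas,
    group_average,
    injection_qc,
    normalize_per_cell,
    sum_projection,
    transform_coords,
)


def plain_annotation(shape=(20, 20, 20)):
    return AnnotationVolume(np.zeros(shape, dtype=np.int32), 25.0)


class TestTransformCoords:
    def test_identity_chain_at_matching_voxel_size_is_identity(self, rng):
        coords = rng.integers(0, 100, (50, 3))
        out, info = transform_coords(coords, TransformChain([Affine.identity()]), (25, 25, 25))
        assert np.allclose(out, coords)
        assert info["out_of_support"] == 0

    def test_pure_translation_shifts_by_exact_voxels(self):
        chain = TransformChain([Affine.translation((250.0, 0.0, 0.0))])
        out, _ = transform_coords(np.array([[4, 5, 6]]), chain, (25, 25, 25))
        assert np.allclose(out, [[14, 5, 6]])  # 250 µm / 25 µm = 10 voxels

    def test_anisotropic_native_voxels_against_matrix_oracle(self):
        native = (5.3, 5.3, 5.0)
        chain = TransformChain([Affine.identity()])
        out, _ = transform_coords(np.array([[100, 100, 100]]), chain, native)
        # hand-computed: 100 voxels × native size / 25 µm
        assert np.allclose(out, [[21.2, 21.2, 20.0]])

    def test_invertible_affine_round_trips(self, rng):
        m = np.eye(4)
        m[:3, :3] = [[1.1, 0.02, 0.0], [0.0, 0.95, 0.03], [0.01, 0.0, 1.05]]
        m[:3, 3] = [100.0, -30.0, 12.0]
        fwd = Affine(m)
        coords = rng.uniform(0, 200, (40, 3))
        mapped, _ = transform_coords(coords, TransformChain([fwd]), (25, 25, 25))
        back, _ = transform_coords(mapped, TransformChain([fwd.inverse()]), (25, 25, 25))
        assert np.allclose(back, coords, atol=1e-6)

    def test_displacement_field_interpolates_and_tallies_outside(self):
        # constant +50 µm AP shift on a small support grid
        offsets = np.zeros((3, 4, 4, 4))
        offsets[0] = 50.0
        field = DisplacementField(offsets, grid_voxel_um=100.0)
        chain = TransformChain([field])
        inside = np.array([[4.0, 4.0, 4.0]])  # 100 µm → grid coord 4: outside [0,3]
        out, n_outside = chain.apply(np.array([[100.0, 100.0, 100.0], [900.0, 0.0, 0.0]]))
        assert np.allclose(out[0], [150.0, 100.0, 100.0])
        assert np.allclose(out[1], [950.0, 0.0, 0.0])  # nearest-edge displacement
        assert n_outside == 1


class TestBinToAtlas:
    def test_conserves_every_in_bounds_count(self, rng):
        ann = plain_annotation()
        coords = rng.uniform(0, 19, (500, 3))
        counts = bin_to_atlas(coords, ann)
        assert counts.total == 500
        assert counts.out_of_bounds_count == 0

    def test_eight_coordinates_into_one_voxel(self):
        ann = plain_annotation()
        coords = np.tile([[5.2, 5.3, 4.8]], (8, 1))
        counts = bin_to_atlas(coords, ann)
        assert counts.grid[5, 5, 5] == 8

    def test_rounding_is_half_up(self):
        ann = plain_annotation()
        counts = bin_to_atlas(np.array([[2.5, 3.49, 3.5]]), ann)
        assert counts.grid[3, 3, 4] == 1

    def test_edge_coordinate_just_outside_is_tallied(self):
        ann = plain_annotation()
        coords = np.array([[19.6, 0.0, 0.0], [19.4, 0.0, 0.0]])  # rounds to 20 (out), 19 (in)
        counts = bin_to_atlas(coords, ann)
        assert counts.out_of_bounds_count == 1
        assert counts.total == 1


class TestNormalizePerCell:
    def test_divides_totals(self):
        grid = np.zeros((4, 4, 4), dtype=np.int64)
        grid[1, 1, 1] = 1000
        dmap = normalize_per_cell(CountsVolume(grid), 100)
        assert dmap.total == pytest.approx(10.0)
        assert dmap.n_cells == 100

    def test_single_cell_is_identity(self):
        grid = np.arange(8, dtype=np.int64).reshape(2, 2, 2)
        dmap = normalize_per_cell(CountsVolume(grid), 1)
        assert np.array_equal(dmap.grid, grid.astype(float))

    @pytest.mark.parametrize("n", [0, -3])
    def test_nonpositive_cell_count_rejected(self, n):
        with pytest.raises(ValueError):
            normalize_per_cell(CountsVolume(np.zeros((2, 2, 2), dtype=np.int64)), n)


class TestInjectionQC:
    def _mask_with_fraction(self, toy_atlas, n_in, n_out):
        annotation, graph, _ = toy_atlas
        target = graph.id_of("SSp-bfd2/3")
        other = graph.id_of("CP")
        mask = np.zeros(annotation.shape, dtype=bool)
        inside = np.argwhere(annotation.id_grid == target)[:n_in]
        outside = np.argwhere(annotation.id_grid == other)[:n_out]
        mask[tuple(inside.T)] = True
        mask[tuple(outside.T)] = True
        return mask

    def test_exactly_eighty_percent_is_included(self, toy_atlas):
        annotation, graph, _ = toy_atlas
        qc = injection_qc(self._mask_with_fraction(toy_atlas, 80, 20), annotation, graph)
        assert qc.fraction_in_targets == pytest.approx(0.80)
        assert qc.included  # the rule is "at least 80%"

    def test_just_below_threshold_is_excluded(self, toy_atlas):
        annotation, graph, _ = toy_atlas
        qc = injection_qc(self._mask_with_fraction(toy_atlas, 79, 21), annotation, graph)
        assert qc.fraction_in_targets == pytest.approx(0.79)
        assert not qc.included

    def test_cube_inside_target_centers_and_fills(self, toy_atlas):
        annotation, graph, _ = toy_atlas
        corner = np.argwhere(annotation.id_grid == graph.id_of("SSp-bfd5"))[0]
        mask = np.zeros(annotation.shape, dtype=bool)
        sl = tuple(slice(c, c + 4) for c in corner)
        mask[sl] = True
        qc = injection_qc(mask, annotation, graph)
        assert qc.fraction_in_targets == 1.0
        assert qc.center_voxel == pytest.approx(tuple(corner + 1.5))
        assert qc.n_voxels == 64
        assert qc.volume_mm3 == pytest.approx(64 * 0.025**3)

    def test_empty_mask_is_an_error(self, toy_atlas):
        annotation, graph, _ = toy_atlas
        with pytest.raises(ValueError, match="empty"):
            injection_qc(np.zeros(annotation.shape, dtype=bool), annotation, graph)

    def test_layers_count_toward_their_region(self, toy_atlas):
        """Voxels annotated with SSs layers satisfy the SSs target via descendants."""
        annotation, graph, _ = toy_atlas
        mask = np.zeros(annotation.shape, dtype=bool)
        voxels = np.argwhere(annotation.id_grid == graph.id_of("SSs6"))[:50]
        mask[tuple(voxels.T)] = True
        qc = injection_qc(mask, annotation, graph)
        assert qc.fraction_in_targets == 1.0


class TestGroupAverageAndProjection:
    def _dmap(self, grid, n_cells=1):
        return DensityMap(grid=np.asarray(grid, dtype=float), n_cells=n_cells)

    def test_average_of_identical_maps_is_the_map(self):
        g = np.random.default_rng(0).random((5, 5, 5))
        avg = group_average([self._dmap(g), self._dmap(g), self._dmap(g)])
        assert np.allclose(avg.grid, g)

    def test_single_map_averages_to_itself(self):
        g = np.random.default_rng(1).random((4, 4, 4))
        assert np.allclose(group_average([self._dmap(g)]).grid, g)

    def test_disjoint_support_halves_totals(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 6.0
        b[3, 3, 3] = 2.0
        avg = group_average([self._dmap(a), self._dmap(b)])
        assert avg.grid.sum() == pytest.approx((6.0 + 2.0) / 2)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            group_average([self._dmap(np.zeros((3, 3, 3))), self._dmap(np.zeros((4, 3, 3)))])

    def test_whole_axis_projection_conserves_total(self, rng):
        g = rng.random((6, 7, 8))
        for axis in ("AP", "DV", "ML"):
            assert sum_projection(g, axis).sum() == pytest.approx(g.sum())

    def test_slab_of_five_planes(self, rng):
        g = rng.random((10, 4, 4))
        proj = sum_projection(g, "AP", slab=(2, 7))  # 125 µm at 25 µm voxels
        assert proj.sum() == pytest.approx(g[2:7].sum())

    def test_impulse_projects_to_single_pixel(self):
        g = np.zeros((5, 6, 7))
        g[2, 3, 4] = 1.0
        proj = sum_projection(g, "DV")
        assert proj[2, 4] == 1.0 and proj.sum() == 1.0

    def test_empty_slab_rejected(self):
        with pytest.raises(ValueError, match="slab"):
            sum_projection(np.zeros((5, 5, 5)), "AP", slab=(3, 3))

    def test_group_average_commutes_with_projection(self, rng):
        maps = [self._dmap(rng.random((5, 5, 5))) for _ in range(3)]
        avg_then_proj = sum_projection(group_average(maps).grid, "DV")
        proj_then_avg = np.mean([sum_projection(m.grid, "DV") for m in maps], axis=0)
        assert np.allclose(avg_then_proj, proj_then_avg, rtol=1e-9)
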