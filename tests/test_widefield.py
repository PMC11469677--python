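"""ΔF/F, evoked maps, population averaging and functional topography."""

import numpy as np
import pandas as pd
import pytest

from projquant.synthetic import WidefieldTruth, simulate_widefield_session
from projquant.widefield import (
    EvokedMap,
    compute_dff,
    evoked_map,
    fit_functional_topography,
    frontal_center_of_mass,
    population_average,
    preprocess_movie,
)

SMALL = dict(frame_shape=(36, 112), trials_per_point=2, timing="coarse")


def small_session(**overrides):
    truth = WidefieldTruth(**{**SMALL, **overrides})
    return simulate_widefield_session(truth, seed=3), truth


class TestPreprocess:
    def test_camera_geometry_bins_two_by_two(self):
        movie = np.zeros((3, 256, 320))
        binned, pix, bregma = preprocess_movie(movie, 2, pixel_size_um=31.25,
                                               bregma_pixel=(100.0, 160.0))
        assert binned.shape == (3, 128, 160)
        assert pix == 62.5
        assert bregma == (50.0, 80.0)

    def test_constant_image_unchanged_by_pooling(self):
        movie = np.full((2, 8, 8), 7.0)
        binned, _, _ = preprocess_movie(movie, 2)
        assert np.allclose(binned, 7.0)

    def test_checkerboard_pools_to_half(self):
        frame = np.indices((6, 6)).sum(axis=0) % 2
        binned, _, _ = preprocess_movie(frame[None].astype(float), 2)
        assert np.allclose(binned, 0.5)

    def test_trailing_pixels_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="trailing"):
            binned, _, _ = preprocess_movie(np.zeros((1, 7, 9)), 2)
        assert binned.shape == (1, 3, 4)


class TestComputeDff:
    def test_temporally_constant_movie_gives_zero(self):
        (session, _), _ = small_session(amplitude=0.0, noise_sd=0.0)
        dff, info = compute_dff(session)
        assert np.allclose(dff, 0.0, atol=1e-6)
        assert info["n_nonpositive_f0_pixels"] == 0

    def test_doubling_baseline_gives_dff_of_one(self):
        (session, _), truth = small_session(amplitude=0.0, noise_sd=0.0)
        movie = session.movie.copy()
        movie[:, session.frame_times_ms >= 0] *= 2.0
        session.movie = movie
        dff, _ = compute_dff(session)
        post = dff[:, session.frame_times_ms >= 0]
        assert np.allclose(post, 1.0, atol=1e-6)

    def test_fine_timing_has_thirty_baseline_frames(self):
        # 300 ms baseline at 100 Hz peri-stimulus sampling
        truth = WidefieldTruth(frame_shape=(36, 112), trials_per_point=1, timing="fine")
        session, _ = simulate_widefield_session(truth, seed=0)
        _, info = compute_dff(session, baseline_ms=300)
        assert info["n_baseline_frames"] == 30

    def test_no_baseline_frames_is_an_error(self):
        (session, _), _ = small_session()
        session.frame_times_ms = session.frame_times_ms + 1000.0
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(session)


class TestEvokedMap:
    def test_noise_free_map_equals_template_peak(self):
        (session, struth), truth = small_session(noise_sd=0.0)
        dff, _ = compute_dff(session)
        for gp in range(len(truth.stim_points_mm)):
            em = evoked_map(dff, session, gp)
            rc, cc = struth.centers_px[gp]
            assert em.values[rc, cc] == pytest.approx(truth.amplitude, abs=1e-6)
            assert em.values.max() == pytest.approx(truth.amplitude, abs=1e-6)
            assert em.n_trials == truth.trials_per_point

    def test_linearity_in_dff(self):
        (session, _), _ = small_session(noise_sd=0.0)
        dff, _ = compute_dff(session)
        em1 = evoked_map(dff, session, 0)
        em2 = evoked_map(2.0 * dff, session, 0)
        assert np.allclose(em2.values, 2.0 * em1.values, atol=1e-9)

    def test_unknown_grid_point_is_an_error(self):
        (session, _), _ = small_session()
        dff, _ = compute_dff(session)
        with pytest.raises(ValueError, match="no trials"):
            evoked_map(dff, session, 99)


class TestPopulationAverage:
    def test_trial_weighted_mean(self):
        a = EvokedMap(np.zeros((4, 4)), n_trials=1, grid_point_id=0)
        b = EvokedMap(np.full((4, 4), 4.0), n_trials=3, grid_point_id=0)
        avg = population_average([a, b])
        assert np.allclose(avg.values, 3.0)  # (0·1 + 4·3) / 4
        assert avg.n_trials == 4

    def test_equal_weights_reduce_to_plain_mean(self):
        maps = [EvokedMap(np.full((3, 3), float(v)), n_trials=2, grid_point_id=0)
                for v in (1, 2, 3)]
        assert np.allclose(population_average(maps).values, 2.0)

    def test_single_map_is_itself(self):
        m = EvokedMap(np.arange(9.0).reshape(3, 3), n_trials=5, grid_point_id=1)
        assert np.allclose(population_average([m]).values, m.values)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            population_average([])


class TestCenterOfMass:
    def _session(self):
        (session, struth), truth = small_session(noise_sd=0.0)
        return session, struth, truth

    def test_single_pixel_impulse_returns_that_pixel(self):
        session, _, truth = self._session()
        vals = np.zeros(truth.frame_shape)
        vals[10, 70] = 1.0
        com = frontal_center_of_mass(EvokedMap(vals, 1, 0), session,
                                     mask_origin=(4, 65), mask_shape=(25, 40))
        assert (com.row, com.col) == (10.0, 70.0)
        ap, ml = session.pixel_to_mm(10.0, 70.0)
        assert com.ap_mm == pytest.approx(ap) and com.ml_mm == pytest.approx(ml)

    def test_uniform_map_centers_on_mask(self):
        session, _, truth = self._session()
        com = frontal_center_of_mass(EvokedMap(np.ones(truth.frame_shape), 1, 0), session,
                                     mask_origin=(4, 65), mask_shape=(25, 40))
        assert com.row == pytest.approx(4 + 12.0)  # geometric center of 25 rows
        assert com.col == pytest.approx(65 + 19.5)

    def test_gaussian_bump_recovered_within_a_fifth_pixel(self):
        session, struth, truth = self._session()
        dff, _ = compute_dff(session)
        gp = 0
        em = evoked_map(dff, session, gp)
        com = frontal_center_of_mass(em, session, mask_origin=truth.frontal_mask_origin())
        rc, cc = struth.centers_px[gp]
        assert abs(com.row - rc) <= 0.2 and abs(com.col - cc) <= 0.2

    def test_nonpositive_mask_yields_undefined(self):
        session, _, truth = self._session()
        vals = np.full(truth.frame_shape, -1.0)
        com = frontal_center_of_mass(EvokedMap(vals, 1, 0), session,
                                     mask_origin=(4, 65), mask_shape=(25, 40))
        assert not com.defined and np.isnan(com.ap_mm)

    def test_mask_outside_frame_rejected(self):
        session, _, truth = self._session()
        with pytest.raises(ValueError, match="not inside"):
            frontal_center_of_mass(EvokedMap(np.ones(truth.frame_shape), 1, 0), session,
                                   mask_origin=(20, 100), mask_shape=(25, 40))


class TestSessionIO:
    def test_hdf5_round_trip(self, tmp_path):
        from projquant.widefield import load_session, save_session

        (session, _), _ = small_session(trials_per_point=1)
        path = tmp_path / "session.h5"
        save_session(session, path)
        again = load_session(path)
        assert np.allclose(again.movie, session.movie)
        assert np.array_equal(again.frame_times_ms, session.frame_times_ms)
        pd.testing.assert_frame_equal(
            again.stim_log.astype({"trial": int, "grid_point_id": int}),
            session.stim_log.astype({"trial": int, "grid_point_id": int}),
        )
        assert again.pixel_size_um == session.pixel_size_um
        assert again.bregma_pixel == session.bregma_pixel


class TestFunctionalFit:
    def test_collinear_mice_recover_the_line(self):
        rows = []
        for mouse in ("m1", "m2"):
            for ml in (2.5, 3.0, 3.5, 4.0):
                rows.append({"mouse_id": mouse, "stim_ml_mm": ml,
                             "com_ap_mm": 0.25 + 0.5 * ml})
        pooled, per_mouse = fit_functional_topography(pd.DataFrame(rows))
        assert pooled.slope == pytest.approx(0.5)
        assert pooled.r == pytest.approx(1.0)
        assert per_mouse["m1"].slope == pytest.approx(0.5)

    def test_single_point_mouse_contributes_but_gets_no_line(self):
        rows = [
            {"mouse_id": "m1", "stim_ml_mm": 2.5, "com_ap_mm": 1.5},
            {"mouse_id": "m1", "stim_ml_mm": 3.0, "com_ap_mm": 1.75},
            {"mouse_id": "m1", "stim_ml_mm": 3.5, "com_ap_mm": 2.0},
            {"mouse_id": "m2", "stim_ml_mm": 4.0, "com_ap_mm": 2.25},
        ]
        pooled, per_mouse = fit_functional_topography(pd.DataFrame(rows))
        assert pooled.n == 4
        assert per_mouse["m2"] is None

    def test_undefined_responses_dropped(self):
        rows = [
            {"mouse_id": "m1", "stim_ml_mm": 2.5, "com_ap_mm": 1.5},
            {"mouse_id": "m1", "stim_ml_mm": 3.0, "com_ap_mm": np.nan},
            {"mouse_id": "m1", "stim_ml_mm": 3.5, "com_ap_mm": 2.0},
            {"mouse_id": "m1", "stim_ml_mm": 4.0, "com_ap_mm": 2.25},
        ]
        pooled, _ = fit_functional_topography(pd.DataFrame(rows))
        assert pooled.n == 3
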