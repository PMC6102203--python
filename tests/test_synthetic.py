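"""The synthetic-microscopy generator: determinism, ground-truth invariants,
motion calibration and the dye-diffusion series."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import microtem as mt
from microtem.regions import GEL
from conftest import small_config


class TestLayout:
    def test_bands_partition_the_field_of_view(self, small_cfg):
        layout = mt.generate_layout(small_cfg)
        labels = mt.define_regions(layout)
        assert labels.shape == layout.shape
        assert set(np.unique(labels)) <= {0, 1, 2}
        # every pixel has exactly one label by construction; check the split
        x = layout.x_um(np.arange(layout.shape[1]))
        row = labels[0]
        assert (row[x > 0] == 2).all()
        assert (row[x < -layout.barrier_thickness_um] == 0).all()
        assert (row[(x >= -layout.barrier_thickness_um) & (x <= 0)] == 1).all()

    def test_barrier_band_width_in_pixels(self):
        cfg = small_config(pixel_size_um=0.8)
        layout = mt.generate_layout(cfg)
        labels = mt.define_regions(layout)
        assert (labels[0] == 1).sum() == pytest.approx(40.0 / 0.8, abs=1)

    def test_pillar_windows_inside_bounds(self, small_cfg):
        layout = mt.generate_layout(small_cfg)
        ny, nx = layout.shape
        assert layout.pillar_windows
        for (y0, y1, x0, x1) in layout.pillar_windows:
            assert 0 <= y0 < y1 <= ny
            assert 0 <= x0 < x1 <= nx

    def test_barrier_wider_than_fov_rejected(self):
        with pytest.raises(ValueError):
            small_config(fov_width_um=30.0, barrier_thickness_um=40.0)


class TestMotionGroundTruth:
    def test_same_seed_is_bit_identical(self, small_cfg):
        s1, t1 = mt.simulate_timelapse(small_cfg)
        s2, t2 = mt.simulate_timelapse(small_cfg)
        np.testing.assert_array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(t1.tracks, t2.tracks)
        pd.testing.assert_frame_equal(t1.crossings, t2.crossings)
        np.testing.assert_array_equal(t1.drift_px, t2.drift_px)

    def test_zero_crossing_probability_means_no_events(self):
        cfg = small_config(p_cross_per_frame=0.0, n_frames=10)
        truth = mt.simulate_tracks(cfg)
        assert len(truth.crossings) == 0
        assert not (truth.tracks["region"] == GEL).any()

    def test_gel_entry_is_irreversible(self):
        cfg = small_config(p_cross_per_frame=0.5, n_frames=20, n_cells=10, seed=3)
        truth = mt.simulate_tracks(cfg)
        assert len(truth.crossings) > 0
        for _, grp in truth.tracks.groupby("track_id"):
            regions = list(grp.sort_values("frame")["region"])
            if GEL in regions:
                first = regions.index(GEL)
                assert all(r == GEL for r in regions[first:])

    def test_mean_frame_displacement_matches_speed(self):
        # 0.5 um/min at 20-min sampling -> 10 um mean step
        speeds = {"channel": 0.5, "barrier": 0.5, "gel": 0.5}
        cfg = small_config(n_cells=40, n_frames=40, fov_length_um=413.0,
                           speed_by_region_um_per_min=speeds,
                           p_cross_per_frame=0.0, seed=5)
        truth = mt.simulate_tracks(cfg)
        disp = []
        for _, grp in truth.tracks.groupby("track_id"):
            grp = grp.sort_values("frame")
            disp.extend(np.hypot(np.diff(grp["x_um"]), np.diff(grp["y_um"])))
        disp = np.asarray(disp)
        # CLT bound: mean step 10, sd = cv*10 = 3, n ~ 1560
        assert disp.mean() == pytest.approx(10.0, abs=3 * 3.0 / np.sqrt(len(disp)) + 0.1)

    def test_drift_is_bounded(self, small_sample):
        _, truth = small_sample
        assert np.all(np.abs(truth.drift_px) <= truth.config.drift_amplitude_px)
        assert tuple(truth.drift_px[0]) == (0.0, 0.0)

    def test_crossing_events_only_at_hotspots_when_gated(self):
        cfg = small_config(p_cross_per_frame=0.8, n_frames=40, n_cells=25,
                           fov_length_um=413.0,
                           hotspot_centers_yz_um=[(100.0, 10.0)],
                           hotspot_radius_um=40.0, seed=9)
        truth = mt.simulate_tracks(cfg)
        assert len(truth.crossings) > 0
        d = np.hypot(truth.crossings["y_um"] - 100.0, truth.crossings["z_um"] - 10.0)
        assert (d <= 40.0).all()


class TestRendering:
    def test_rendered_nucleus_matches_table_within_a_pixel(self, noisefree_frame):
        cfg, truth, bf, gfp = noisefree_frame
        proj = mt.project_gfp(gfp)
        for _, row in truth.positions(0).iterrows():
            mask = truth.mask(0, int(row["track_id"]))
            cx, cy, fallback = mt.detect_nucleus(mask, proj)
            assert not fallback
            assert abs(cx * cfg.pixel_size_um - (row["nucleus_x_um"] - cfg.x_min_um)) \
                <= cfg.pixel_size_um
            assert abs(cy * cfg.pixel_size_um - row["nucleus_y_um"]) <= cfg.pixel_size_um

    def test_gfp_brightest_at_cell_z_level(self, noisefree_frame):
        cfg, truth, bf, gfp = noisefree_frame
        for _, row in truth.positions(0).iterrows():
            mask = truth.mask(0, int(row["track_id"]))
            z_est = mt.estimate_z(mask, gfp, cfg.z_step_um)
            assert z_est == pytest.approx(row["z_um"], abs=cfg.z_step_um)

    def test_brightfield_edge_sharpest_at_cell_level(self, noisefree_frame):
        cfg, truth, bf, gfp = noisefree_frame
        from scipy import ndimage
        row = truth.positions(0).iloc[0]
        mask = truth.mask(0, int(row["track_id"]))
        boundary = mask ^ ndimage.binary_erosion(mask)
        z_cell = int(round(row["z_um"] / cfg.z_step_um))
        grads = [np.mean(ndimage.gaussian_gradient_magnitude(bf[z], 1.0)[boundary])
                 for z in range(cfg.z_slices)]
        far = [g for z, g in enumerate(grads)
               if abs(z - z_cell) * cfg.z_step_um > 10]
        assert max(grads[max(0, z_cell - 1):z_cell + 2]) > 2 * max(far)


class TestDextranSeries:
    def test_zero_permeability_is_constant(self):
        s = mt.simulate_dextran_series(0.0, noise_sd=0.0)
        assert np.allclose(s["intensity"], s["intensity"][0])

    def test_noise_free_series_strictly_increasing_early(self):
        s = mt.simulate_dextran_series(12e-6, noise_sd=0.0)
        early = s["t_s"] <= 15 * 60
        assert np.all(np.diff(s["intensity"][early]) > 0)

    def test_round_trip_recovers_p_true_within_one_percent(self):
        for p_true in (5e-6, 12e-6, 59e-6):
            s = mt.simulate_dextran_series(p_true, noise_sd=0.0)
            fit = mt.fit_permeability(s["t_s"], s["intensity"],
                                      I_b=s["I_background"],
                                      diameter_um=s["diameter_um"])
            assert fit.P_cm_s == pytest.approx(p_true, rel=0.01)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            mt.simulate_dextran_series(-1e-6)


class TestDataset:
    def test_write_dataset_round_trips(self, small_sample, tmp_path):
        series, truth = small_sample
        paths = mt.write_dataset(series, truth, tmp_path)
        back = mt.read_stack(paths["stack"])
        np.testing.assert_array_equal(back.data, series.data)
        assert back.channels == series.channels
        tracks = pd.read_csv(paths["tracks"])
        assert len(tracks) == len(truth.tracks)
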