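"""Region assignment and trajectory linking."""

import numpy as np
import pandas as pd
import pytest

import microtem as mt
from microtem.regions import BARRIER, CHANNEL, GEL, RegionLayout
from microtem.tracking import link_tracks


LAYOUT = RegionLayout(shape=(200, 250), pixel_size_um=1.0, x_origin_um=-160.0)


def det_frame(points, start_label=1):
    return pd.DataFrame({
        "label": np.arange(start_label, start_label + len(points)),
        "nucleus_x_um": [p[0] for p in points],
        "nucleus_y_um": [p[1] for p in points],
        "z_um": 0.0,
        "area_um2": 100.0,
        "nucleus_fallback": False,
    })


class TestRegions:
    @pytest.mark.parametrize("x,expected", [
        (-60.0, CHANNEL), (-10.0, BARRIER), (10.0, GEL),
        (0.0, BARRIER),    # closed upper bound
        (-40.0, BARRIER),  # closed lower bound
    ])
    def test_band_rule(self, x, expected):
        assert mt.assign_region((x, 50.0), LAYOUT) == expected

    def test_partition_covers_every_pixel(self):
        labels = mt.define_regions(LAYOUT)
        areas = [(labels == c).sum() for c in (0, 1, 2)]
        assert sum(areas) == labels.size
        assert all(a > 0 for a in areas)

    def test_point_outside_fov_is_an_error(self):
        with pytest.raises(ValueError):
            mt.assign_region((500.0, 50.0), LAYOUT)

    def test_ground_truth_regions_match_assignment(self):
        # the region label is decided by the nucleus, the tracked point
        from conftest import small_config
        cfg = small_config(n_cells=8, n_frames=8, p_cross_per_frame=0.3, seed=41)
        truth = mt.simulate_tracks(cfg)
        for _, row in truth.tracks.iterrows():
            assert mt.region_of_x(row["nucleus_x_um"],
                                  cfg.barrier_thickness_um) == row["region"]


class TestLinkTracks:
    def test_two_distant_cells_keep_identities(self):
        frames = {}
        for t in range(5):
            frames[t] = det_frame([(-100.0 + t, 20.0), (-100.0 + t, 120.0)])
        tracks = link_tracks(frames, gate_um_per_frame=30.0)
        assert tracks["track_id"].nunique() == 2
        for _, grp in tracks.groupby("track_id"):
            assert len(grp) == 5
            assert grp["nucleus_fallback"].eq(False).all()
            assert np.ptp(grp["y_um"]) == 0.0

    def test_departure_ends_track_and_entrant_gets_new_id(self):
        frames = {
            0: det_frame([(-100.0, 20.0)]),
            1: det_frame([(-100.0, 20.0)]),
            2: det_frame([]),            # cell left the field of view
            3: det_frame([]),
            4: det_frame([]),
            5: det_frame([(-100.0, 20.0)]),  # re-entry beyond max_gap
        }
        tracks = link_tracks(frames, gate_um_per_frame=30.0, max_gap=2)
        ids = tracks["track_id"].unique()
        assert len(ids) == 2
        first = tracks[tracks["track_id"] == ids[0]]
        assert first["frame"].max() == 1

    def test_gap_bridging_within_max_gap(self):
        frames = {
            0: det_frame([(-100.0, 20.0)]),
            1: det_frame([]),
            2: det_frame([(-98.0, 22.0)]),
        }
        tracks = link_tracks(frames, gate_um_per_frame=30.0, max_gap=2)
        assert tracks["track_id"].nunique() == 1

    def test_gate_rejects_large_jumps(self):
        frames = {
            0: det_frame([(-100.0, 20.0)]),
            1: det_frame([(-100.0, 90.0)]),  # 70 um jump > gate
        }
        tracks = link_tracks(frames, gate_um_per_frame=30.0)
        assert tracks["track_id"].nunique() == 2

    def test_single_detection_per_frame_with_huge_gate_is_one_track(self):
        frames = {t: det_frame([(-100.0 + 17 * t, 10.0 + 23 * t)])
                  for t in range(6)}
        tracks = link_tracks(frames, gate_um_per_frame=1e9)
        assert tracks["track_id"].nunique() == 1

    def test_time_reversal_gives_same_partition(self, rng):
        # well-separated random walkers; linking must not depend on direction
        n, T = 5, 8
        starts = np.column_stack([rng.uniform(-150, -20, n),
                                  np.linspace(20, 180, n)])
        pos = {t: starts + rng.normal(0, 3, (n, 2)) + np.array([t * 2.0, 0])
               for t in range(T)}
        fwd = link_tracks({t: det_frame(list(map(tuple, pos[t]))) for t in range(T)},
                          gate_um_per_frame=20.0)
        rev = link_tracks({T - 1 - t: det_frame(list(map(tuple, pos[t])))
                           for t in range(T)}, gate_um_per_frame=20.0)

        def partition(table):
            groups = set()
            for _, grp in table.groupby("track_id"):
                groups.add(frozenset(zip(grp["frame"], np.round(grp["x_um"], 6))))
            return groups

        rev = rev.copy()
        rev["frame"] = T - 1 - rev["frame"]
        assert partition(fwd) == partition(rev)

    def test_ground_truth_correspondence_with_hungarian_cross_check(self, rng):
        """20 non-crossing tracks (inter-track spacing larger than the gate,
        within-track steps smaller) must link with zero identity switches,
        agreeing with an optimal-assignment oracle."""
        from scipy.optimize import linear_sum_assignment

        n, T = 20, 10
        cy, cx = np.mgrid[0:4, 0:5]
        centers = np.column_stack([(-150 + 50 * cx.ravel()),
                                   (20 + 50 * cy.ravel())]).astype(float)
        pos = {t: centers + rng.uniform(-7, 7, (n, 2)) for t in range(T)}
        frames = {t: det_frame(list(map(tuple, pos[t]))) for t in range(T)}
        tracks = link_tracks(frames, gate_um_per_frame=25.0)
        assert tracks["track_id"].nunique() == n

        switches = 0
        for tid, grp in tracks.groupby("track_id"):
            gt_ids = set()
            for _, row in grp.iterrows():
                d = np.hypot(centers[:, 0] - row["x_um"], centers[:, 1] - row["y_um"])
                gt_ids.add(int(np.argmin(d)))
            switches += len(gt_ids) - 1
        assert switches == 0

        # Hungarian oracle frame-to-frame: optimal assignment is the identity
        for t in range(T - 1):
            cost = np.linalg.norm(pos[t][:, None] - pos[t + 1][None], axis=2)
            rows, cols = linear_sum_assignment(cost)
            assert (cols[np.argsort(rows)] == np.arange(n)).all()

    def test_override_wins_and_unknown_reference_is_an_error(self):
        frames = {0: det_frame([(-100.0, 20.0)]), 1: det_frame([(-99.0, 21.0)])}
        overrides = pd.DataFrame({"frame": [1], "label": [1], "track_id": [99]})
        tracks = link_tracks(frames, overrides=overrides)
        assert set(tracks["track_id"]) == {0, 99}
        bad = pd.DataFrame({"frame": [5], "label": [1], "track_id": [0]})
        with pytest.raises(ValueError, match="unknown detection"):
            link_tracks(frames, overrides=bad)

    def test_duplicate_frames_rejected_in_velocities(self):
        table = pd.DataFrame({
            "track_id": [0, 0], "frame": [1, 1], "t_min": [20.0, 20.0],
            "x_um": [0.0, 1.0], "y_um": [0.0, 0.0], "z_um": [0, 0],
            "region": ["channel"] * 2,
        })
        with pytest.raises(ValueError, match="duplicate"):
            mt.velocities(table)
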