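"""Trajectory behaviour classification and its exhaustive rule oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import microtem as mt
from microtem.behavior import TYPE_I, TYPE_II, TYPE_III, classify_behavior


def track_from_regions(regions, track_id=0):
    n = len(regions)
    return pd.DataFrame({
        "track_id": track_id, "frame": range(n),
        "t_min": [20.0 * i for i in range(n)],
        "x_um": 0.0, "y_um": [10.0 * i for i in range(n)],
        "z_um": [float(i) for i in range(n)],
        "region": regions,
    })


def oracle_smooth(regions, min_visit=2):
    """Independent re-statement of the visit rule via run-length groups."""
    runs = [(r, len(list(g))) for r, g in itertools.groupby(regions)]
    long_runs = [i for i, (_, n) in enumerate(runs) if n >= min_visit]
    if not long_runs:
        return [regions[0]] * len(regions)
    out = []
    for i, (r, n) in enumerate(runs):
        if n >= min_visit:
            label = r
        else:
            prev = [j for j in long_runs if j < i]
            label = runs[prev[-1]][0] if prev else runs[min(
                j for j in long_runs if j > i)][0]
        out.extend([label] * n)
    return out


def oracle_type(regions, min_visit=2):
    sm = oracle_smooth(regions, min_visit)
    if "gel" in sm:
        return TYPE_I
    if sm[-1] == "barrier":
        return TYPE_II
    return TYPE_III


class TestClassifyBehavior:
    @pytest.mark.parametrize("regions,expected", [
        (["channel", "channel", "barrier", "barrier", "gel", "gel"], TYPE_I),
        (["channel", "barrier", "barrier", "barrier"], TYPE_II),
        (["channel", "barrier", "barrier", "channel", "channel"], TYPE_III),
        (["channel", "channel", "channel"], TYPE_III),
        # single-frame gel flicker is noise, not a crossing
        (["channel", "channel", "gel", "channel", "channel"], TYPE_III),
    ])
    def test_canonical_sequences(self, regions, expected):
        rec = classify_behavior(track_from_regions(regions))
        assert rec.type == expected

    def test_type_i_carries_crossing_position(self):
        regions = ["channel", "barrier", "gel", "gel"]
        rec = classify_behavior(track_from_regions(regions))
        assert rec.type == TYPE_I
        assert rec.first_gel_frame == 2
        assert rec.crossing_y_um == 20.0
        assert rec.crossing_z_um == 2.0

    def test_non_type_i_has_no_crossing_position(self):
        rec = classify_behavior(track_from_regions(["channel", "barrier", "barrier"]))
        assert rec.first_gel_frame is None
        assert rec.crossing_y_um is None

    def test_short_tracks_are_excluded(self):
        assert classify_behavior(track_from_regions(["gel"])) is None

    def test_exhaustive_enumeration_matches_oracle(self):
        """All region strings of length 2..6: the classifier must be
        exhaustive, mutually exclusive, and equal to the independent oracle."""
        alphabet = ["channel", "barrier", "gel"]
        for n in range(2, 7):
            for regions in itertools.product(alphabet, repeat=n):
                rec = classify_behavior(track_from_regions(list(regions)))
                assert rec.type in (TYPE_I, TYPE_II, TYPE_III)
                assert rec.type == oracle_type(list(regions)), regions

    def test_smoothing_matches_oracle_exhaustively(self):
        alphabet = ["channel", "barrier", "gel"]
        for n in range(1, 6):
            for regions in itertools.product(alphabet, repeat=n):
                assert mt.smooth_regions(list(regions)) == oracle_smooth(list(regions)), regions


class TestCountSeries:
    def _tracks(self, region_lists):
        return pd.concat(
            [track_from_regions(r, track_id=i) for i, r in enumerate(region_lists)],
            ignore_index=True)

    def test_constant_counts(self):
        tracks = self._tracks([["channel"] * 3, ["barrier"] * 3])
        n_t, n_av = mt.count_series(tracks, 3, "total")
        assert list(n_t) == [2, 2, 2]
        assert n_av == 2.0

    def test_arithmetic_mean(self):
        # counts 1,2,3 -> N_av = 2
        tracks = self._tracks([
            ["channel"] * 3,
            ["channel", "channel", "channel"],
            ["channel", "channel", "channel"],
        ])
        # restrict presence by slicing frames
        t = pd.concat([
            track_from_regions(["channel"] * 3, 0),
            track_from_regions(["channel"] * 2, 1).assign(frame=[1, 2]),
            track_from_regions(["channel"] * 1, 2).assign(frame=[2]),
        ], ignore_index=True)
        n_t, n_av = mt.count_series(t, 3, "total")
        assert list(n_t) == [1, 2, 3]
        assert n_av == 2.0

    def test_ext_is_cumulative_and_monotone(self):
        tracks = self._tracks([
            ["channel", "barrier", "gel", "gel", "gel"],
            ["channel"] * 5,
        ])
        n_t, n_av = mt.count_series(tracks, 5, "ext")
        assert list(n_t) == [0, 0, 1, 1, 1]
        assert n_av == pytest.approx(0.6)
        assert (np.diff(n_t) >= 0).all()

    def test_gel_count_variant_is_per_frame_not_cumulative(self):
        tracks = self._tracks([
            ["channel", "channel", "barrier", "barrier", "gel", "gel"],
            ["channel"] * 6,
        ])
        n_t, _ = mt.count_series(tracks, 6, "gel")
        assert list(n_t) == [0, 0, 0, 0, 1, 1]
        # a track ending early leaves the gel count, unlike the cumulative ext
        t2 = pd.concat([
            track_from_regions(["channel", "channel", "gel", "gel"], 0),
            track_from_regions(["channel"] * 6, 1),
        ], ignore_index=True)
        gel_t, _ = mt.count_series(t2, 6, "gel")
        ext_t, _ = mt.count_series(t2, 6, "ext")
        assert list(gel_t) == [0, 0, 1, 1, 0, 0]
        assert list(ext_t) == [0, 0, 1, 1, 1, 1]

    def test_fixture_counts_match_ground_truth_tally(self):
        from conftest import small_config
        cfg = small_config(n_cells=10, n_frames=12, p_cross_per_frame=0.2, seed=47)
        truth = mt.simulate_tracks(cfg)
        # ground-truth raw tally (no smoothing needed: truth has no flicker
        # shorter than real visits, so compare with min_visit=1)
        n_t, _ = mt.count_series(truth.tracks, cfg.n_frames, "barrier", min_visit=1)
        expected = truth.tracks.groupby("frame")["region"].apply(
            lambda s: (s == "barrier").sum())
        assert list(n_t) == list(expected)


class TestRatios:
    def make_stats(self, ext, tot, bar):
        return mt.SampleStats(n_frames=45, n_t_tot=np.zeros(1),
                              n_t_barrier=np.zeros(1), n_t_ext=np.zeros(1),
                              N_av_tot=tot, N_av_barrier=bar, N_av_ext=ext)

    def test_no_transmigration_flag(self):
        r = mt.transmigration_ratios(self.make_stats(0.0, 14.0, 5.0))
        assert r.no_transmigration
        assert r.r_tot == 0.0 and r.r_barrier == 0.0

    def test_published_scale_examples(self):
        r = mt.transmigration_ratios(self.make_stats(1.0, 14.3, 5.0))
        assert r.r_tot == pytest.approx(0.07, abs=0.001)
        r = mt.transmigration_ratios(self.make_stats(1.7, 24.0, 5.0))
        assert r.r_barrier == pytest.approx(0.34, abs=0.001)

    def test_zero_denominator_flags_not_raises(self):
        r = mt.transmigration_ratios(self.make_stats(1.0, 0.0, 0.0))
        assert not r.no_transmigration
        assert np.isnan(r.r_tot) and np.isnan(r.r_barrier)
        assert len(r.flags) == 2

    def test_barrier_ratio_dominates_total_ratio(self):
        # whenever N_av_barrier <= N_av_tot
        s = self.make_stats(1.3, 20.0, 4.0)
        r = mt.transmigration_ratios(s)
        assert r.r_barrier >= r.r_tot


class TestZeroInterceptFit:
    def test_collinear_points(self):
        slope, se = mt.fit_zero_intercept([1.0, 2.0], [0.34, 0.68])
        assert slope == pytest.approx(0.34)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # sum(xy)/sum(x^2) = (1 + 2) / (1 + 4) = 0.6
        slope, se = mt.fit_zero_intercept([1.0, 2.0], [1.0, 1.0])
        assert slope == pytest.approx(0.6)

    def test_matches_grid_search_minimizer(self, rng):
        x = rng.uniform(1, 30, 12)
        y = 0.34 * x + rng.normal(0, 0.5, 12)
        slope, _ = mt.fit_zero_intercept(x, y)
        grid = np.linspace(slope - 0.05, slope + 0.05, 200001)
        sse = ((y[None, :] - grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        assert slope == pytest.approx(grid[np.argmin(sse)], abs=1e-6)

    def test_all_x_zero_is_an_error(self):
        with pytest.raises(ValueError):
            mt.fit_zero_intercept([0.0, 0.0], [1.0, 2.0])
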