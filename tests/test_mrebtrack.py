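"""Spot detection, linking, persistence filtering and MreB activity."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import savgol_filter

from envgrowth import mrebtrack as mt
from envgrowth import synthgen


def straight_track(track_id, n_points, end_to_end, t0=0.0, dt_s=1.0, origin=(0.0, 0.0)):
    """Evenly spaced straight track (Savitzky-Golay reproduces it exactly)."""
    s = np.linspace(0.0, end_to_end, n_points)
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.arange(n_points),
            "t_s": t0 + dt_s * np.arange(n_points),
            "x_um": origin[0] + s,
            "y_um": origin[1] + np.zeros(n_points),
        }
    )


class TestDetection:
    def test_blank_frame(self):
        assert len(mt.detect_spots(np.zeros((64, 64)), 0.05)) == 0

    def test_five_spots_recovered_subpixel(self):
        px = 0.05
        truth = np.array(
            [[0.8, 0.8], [1.6, 0.9], [0.9, 1.7], [2.4, 1.9], [1.7, 2.6]]
        )
        img = synthgen.render_spot_frame(truth, px, (64, 64), amplitude=1.0,
                                         noise_sigma=0.1, seed=4)
        found = mt.detect_spots(img, px)
        assert len(found) == 5
        for t in truth:
            d = np.linalg.norm(found - t, axis=1).min()
            assert d < 0.03

    def test_unresolved_pair_merges(self):
        px = 0.05
        pair = np.array([[1.0, 1.0], [1.05, 1.0]])  # below the 0.15 um spot size
        img = synthgen.render_spot_frame(pair, px, (48, 48))
        assert len(mt.detect_spots(img, px)) <= 1


class TestLinking:
    def test_single_drifting_spot_one_track(self):
        rows = [(f, float(f), 0.03 * f, 0.5) for f in range(20)]
        spots = pd.DataFrame(rows, columns=["frame", "t_s", "x_um", "y_um"])
        linked = mt.link_tracks(spots, search_radius=0.06, max_gaps=1)
        assert linked["track_id"].nunique() == 1

    def test_radius_violation_splits(self):
        x = [0.0, 0.03, 0.06, 0.26, 0.29, 0.32]  # 0.2 um jump mid-way
        spots = pd.DataFrame(
            {"frame": range(6), "t_s": np.arange(6.0), "x_um": x, "y_um": 0.0}
        )
        linked = mt.link_tracks(spots, search_radius=0.06, max_gaps=1)
        assert linked["track_id"].nunique() == 2

    def test_gap_closing(self):
        spots = pd.DataFrame(
            {"frame": [0, 1, 3, 4], "t_s": [0.0, 1.0, 3.0, 4.0],
             "x_um": [0.0, 0.02, 0.06, 0.08], "y_um": 0.0}
        )
        linked = mt.link_tracks(spots, search_radius=0.06, max_gaps=1)
        assert linked["track_id"].nunique() == 1

    def test_noiseless_scene_matches_generator(self):
        scen = synthgen.MrebScenario(localization_noise=0.0, track_density=0.05,
                                     seed=12)
        spots = synthgen.simulate_mreb_tracks(scen, 100.0, 10.0)
        assert spots["track_id"].nunique() >= 10
        linked = mt.link_tracks(spots.drop(columns=["track_id"]),
                                search_radius=0.06, max_gaps=1)
        # identical partition: every reconstructed track = one true track
        merged = linked.merge(
            spots, on=["frame", "t_s", "x_um", "y_um"], suffixes=("_new", "_true")
        )
        grouping = merged.groupby("track_id_true")["track_id_new"].nunique()
        assert (grouping == 1).all()
        assert merged["track_id_new"].nunique() == merged["track_id_true"].nunique()


class TestPersistenceFilter:
    def test_persistence_rule_examples(self):
        tracks = pd.concat(
            [
                straight_track(0, 8, 0.25),   # 7 steps, e2e 0.25 -> keep
                straight_track(1, 11, 0.15),  # 10 steps but confined -> reject
                straight_track(2, 7, 0.50),   # only 6 steps -> reject
            ]
        )
        kept = mt.filter_tracks(tracks)
        assert [t.track_id for t in kept] == [0]

    def test_brute_force_oracle_1000_tracks(self):
        rng = np.random.default_rng(99)
        frames, expected = [], set()
        for tid in range(1000):
            n = int(rng.integers(3, 16))
            e2e = float(rng.uniform(0.0, 0.5))
            jitter = rng.normal(0.0, rng.uniform(0, 0.03), size=(n, 2))
            s = np.linspace(0.0, e2e, n)
            x = s + jitter[:, 0]
            y = jitter[:, 1]
            frames.append(
                pd.DataFrame({"track_id": tid, "frame": np.arange(n),
                              "t_s": np.arange(float(n)), "x_um": x, "y_um": y})
            )
            # independent literal re-application of the rule
            if n >= 7:
                xs = savgol_filter(x, 7, 2)
                ys = savgol_filter(y, 7, 2)
            else:
                xs, ys = x, y
            if (n - 1) >= 7 and np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]) >= 0.2:
                expected.add(tid)
        kept = {t.track_id for t in mt.filter_tracks(pd.concat(frames))}
        assert kept == expected

    def test_stats_invariants(self):
        tr = mt.track_stats(straight_track(0, 12, 0.4))
        assert tr.n_steps == 11
        assert tr.end_to_end_um <= tr.path_length_um + 1e-12
        assert tr.end_to_end_um == pytest.approx(0.4, rel=1e-9)


class TestActivity:
    def test_no_tracks_zero(self):
        series = mt.activity([], 10.0, 5.0)
        assert np.all(series.activity == 0.0)

    def test_arithmetic_example(self):
        # 3 tracks x 0.5 um in one 1-min window over 10 um^2 -> 0.15
        tracks = [
            mt.track_stats(straight_track(i, 31, 0.5, dt_s=2.0, origin=(i, 0)))
            for i in range(3)
        ]
        series = mt.activity(tracks, 10.0, 1.0, window_min=1.0)
        assert series.activity[0] == pytest.approx(0.15, rel=1e-9)

    def test_single_track_exact(self):
        tracks = [mt.track_stats(straight_track(0, 61, 0.6, dt_s=1.0))]
        series = mt.activity(tracks, 10.0, 1.0, window_min=1.0)
        assert series.activity[0] == pytest.approx(0.06, rel=1e-9)

    def test_scales_inverse_with_area(self):
        tracks = [mt.track_stats(straight_track(0, 31, 0.5, dt_s=2.0))]
        a1 = mt.activity(tracks, 10.0, 1.0, window_min=1.0).activity[0]
        a2 = mt.activity(tracks, 20.0, 1.0, window_min=1.0).activity[0]
        assert a1 == pytest.approx(2 * a2, rel=1e-12)

    def test_rigid_transform_invariance(self):
        base = straight_track(0, 31, 0.5, dt_s=2.0)
        a = 1.1
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        xy = base[["x_um", "y_um"]].to_numpy() @ rot.T + np.array([5.0, -3.0])
        moved = base.assign(x_um=xy[:, 0], y_um=xy[:, 1])
        a0 = mt.activity([mt.track_stats(base)], 10.0, 1.0, window_min=1.0).activity[0]
        a1 = mt.activity([mt.track_stats(moved)], 10.0, 1.0, window_min=1.0).activity[0]
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_generator_expectation_recovered(self):
        scen = synthgen.MrebScenario(track_speed=0.6, track_density=2.0 / 3.0,
                                     seed=21)
        assert scen.expected_activity == pytest.approx(0.2)
        spots = synthgen.simulate_mreb_tracks(scen, 50.0, 10.0)
        linked = mt.link_tracks(spots.drop(columns=["track_id"]), 0.06, 1)
        series = mt.activity(mt.filter_tracks(linked), 50.0, 10.0)
        assert series.activity.mean() == pytest.approx(0.2, rel=0.15)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            mt.activity([], 0.0, 5.0)


class TestMotionStop:
    def test_threshold_crossing(self):
        series = mt.MrebActivitySeries(
            window_centers_min=[0, 2, 4, 6, 8],
            activity=[0.2, 0.15, 0.1, 0.07, 0.05],
            segmented_area_um2=10.0,
        )
        assert series.stop_time_min == 6.0

    def test_never_underpasses(self):
        series = mt.MrebActivitySeries(
            window_centers_min=[0, 2, 4],
            activity=[0.2, 0.15, 0.1],
            segmented_area_um2=10.0,
        )
        assert series.stop_time_min is None

    def test_arrest_recovery_end_to_end(self):
        scen = synthgen.MrebScenario(arrest_time=10.0, seed=3)
        spots = synthgen.simulate_mreb_tracks(scen, 50.0, 20.0)
        linked = mt.link_tracks(spots.drop(columns=["track_id"]), 0.06, 1)
        series = mt.activity(mt.filter_tracks(linked), 50.0, 20.0)
        assert series.stop_time_min is not None
        assert 10.0 <= series.stop_time_min <= 12.0
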