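"""Track linking and motility metrics."""

import numpy as np
import pytest

from disperseq import (
    BoxRoi,
    SphereRoi,
    Track,
    TrackSet,
    WalkParams,
    classify_reversal,
    count_transmigrated,
    distance_from_point_timecourse,
    generate_tracks,
    link_centroids,
    track_speed,
    track_straightness,
)
from disperseq.errors import TrackError


def make_track(positions, dt=0.5, track_id=1):
    positions = np.asarray(positions, dtype=float)
    return Track(track_id, np.arange(len(positions)) * dt, positions)


class TestLinkCentroids:
    def test_static_cells_give_constant_tracks(self):
        frame = np.zeros((1, 10, 10), dtype=int)
        frame[0, 2, 2] = 1
        frame[0, 7, 7] = 2
        movie = np.repeat(frame[None], 4, axis=0)
        ts = link_centroids(movie, spacing=(1, 1, 1), frame_interval_min=0.5)
        assert len(ts) == 2
        for tr in ts:
            assert len(tr) == 4
            assert np.allclose(tr.xyz, tr.xyz[0])

    def test_single_moving_cell_reproduces_centroids(self):
        movie = np.zeros((5, 1, 12, 12), dtype=int)
        for t in range(5):
            movie[t, 0, 3 + t, 4] = 1
        ts = link_centroids(movie, spacing=(1, 1, 1), frame_interval_min=1.0)
        tr = ts.get(1)
        assert np.allclose(tr.xyz[:, 1], 3 + np.arange(5))  # y coordinate

    def test_cluster_movie_recovers_ground_truth(self, wt_cluster_noiseless):
        """Static cluster: recovered tracks sit at the voxelized sphere centres."""
        params, movie, truth = wt_cluster_noiseless
        labels = np.repeat(truth.label_movie.labels, 3, axis=0)
        ts = link_centroids(
            labels,
            spacing=movie.spacing,
            frame_interval_min=0.5,
            cell_radius_um=params.cell_radius_um,
        )
        assert len(ts) == params.n_cells
        for tr in ts:
            truth_zyx = truth.positions[0, tr.track_id - 1]
            est_xyz = tr.xyz[0]
            assert np.allclose(est_xyz[::-1], truth_zyx, atol=0.25)  # < voxel size z


class TestSpeedStraightness:
    def test_speed_one_um_steps_every_30s(self):
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5)  # 1 µm per 0.5 min step
        assert track_speed(make_track(pos)) == pytest.approx(2.0)

    def test_stationary_speed_zero(self):
        assert track_speed(make_track(np.zeros((4, 3)))) == 0.0

    def test_speed_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(41)
        pos = rng.normal(size=(30, 3)).cumsum(axis=0)
        tr = make_track(pos, dt=0.4)
        path = sum(
            np.linalg.norm(pos[i + 1] - pos[i]) for i in range(len(pos) - 1)
        )
        assert track_speed(tr) == pytest.approx(path / (29 * 0.4), rel=1e-12)

    def test_straightness_collinear_is_one(self):
        pos = np.outer(np.arange(6), [1.0, 2.0, -1.0])
        assert track_straightness(make_track(pos)) == pytest.approx(1.0)

    def test_straightness_closed_loop_is_zero(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]], float)
        assert track_straightness(make_track(pos)) == 0.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(43)
        pos = rng.normal(size=(20, 3)).cumsum(axis=0)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = pos @ q.T + np.array([5.0, -3.0, 11.0])
        assert track_speed(make_track(moved)) == pytest.approx(track_speed(make_track(pos)))
        assert track_straightness(make_track(moved)) == pytest.approx(
            track_straightness(make_track(pos))
        )

    def test_persistent_ensemble_matches_resimulation_oracle(self):
        """Mean straightness of the persistent walk matches an independent
        step-by-step re-simulation within 2 combined Monte-Carlo SEs."""
        p = WalkParams(persistence=0.8, step_um=1.0, n_tracks=500, n_frames=30, seed=51)
        ts, _ = generate_tracks(p)
        vals = np.array([track_straightness(tr) for tr in ts])

        rng = np.random.default_rng(9151)
        oracle_vals = []
        for _ in range(500):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = [np.zeros(3)]
            for _ in range(29):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                d = 0.8 * d + 0.2 * u
                d /= np.linalg.norm(d)
                pos.append(pos[-1] + d)
            pos = np.asarray(pos)
            path = np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))
            oracle_vals.append(np.linalg.norm(pos[-1] - pos[0]) / path)
        oracle_vals = np.asarray(oracle_vals)
        se = np.sqrt(
            vals.var(ddof=1) / vals.size + oracle_vals.var(ddof=1) / oracle_vals.size
        )
        assert abs(vals.mean() - oracle_vals.mean()) < 2 * se

    def test_short_track_rejected(self):
        with pytest.raises(TrackError):
            track_speed(make_track(np.zeros((1, 3))))


class TestDistanceTimecourse:
    def test_all_at_reference_gives_zeros(self):
        ts = TrackSet.from_tracks(
            [make_track(np.full((4, 3), 2.0), track_id=i) for i in (1, 2)]
        )
        out = distance_from_point_timecourse(ts, (2.0, 2.0, 2.0))
        assert np.allclose(out["mean"], 0.0)

    def test_relative_mode_first_value_one(self):
        rng = np.random.default_rng(44)
        ts = TrackSet.from_tracks(
            [make_track(rng.normal(5, 1, size=(6, 3)), track_id=i) for i in range(1, 4)]
        )
        out = distance_from_point_timecourse(ts, (0, 0, 0), relative=True)
        assert out.loc[out["t"] == 0.0, "mean"].iloc[0] == pytest.approx(1.0)

    def test_outward_walkers_exceed_random_walkers(self):
        directed, _ = generate_tracks(
            WalkParams(mode="directed", bias_target=None, bias_strength=0.8,
                       persistence=0.8, n_tracks=30, n_frames=30, seed=61)
        )
        random_walk, _ = generate_tracks(
            WalkParams(mode="persistent", persistence=0.0, n_tracks=30, n_frames=30, seed=62)
        )
        d_out = distance_from_point_timecourse(directed, (0, 0, 0))
        d_rand = distance_from_point_timecourse(random_walk, (0, 0, 0))
        assert np.all(np.diff(d_out["mean"]) > 0)
        assert d_out["mean"].iloc[-1] > d_rand["mean"].iloc[-1]


class TestReversalAndTransmigration:
    def test_stationary_inside_roi_is_not_reversal(self):
        roi = BoxRoi((-1, -1, -1), (1, 1, 1))
        tr = make_track(np.zeros((8, 3)))
        assert classify_reversal(tr, roi, t_pulse=0.5, window=2.0) is False

    def test_exit_after_pulse_is_reversal(self):
        roi = BoxRoi((-1, -1, -1), (1, 1, 1))
        pos = np.zeros((8, 3))
        pos[3:, 0] = 5.0
        tr = make_track(pos)
        assert classify_reversal(tr, roi, t_pulse=0.5, window=2.0) is True

    def test_track_not_covering_window_raises(self):
        roi = BoxRoi((-1, -1, -1), (1, 1, 1))
        with pytest.raises(TrackError):
            classify_reversal(make_track(np.zeros((3, 3))), roi, t_pulse=0.5, window=5.0)

    def test_reversal_fraction_matches_containment_oracle(self):
        roi = BoxRoi((-3, -3, -3), (3, 3, 3))
        ts, _ = generate_tracks(
            WalkParams(mode="directed", bias_target=None, bias_strength=0.6,
                       start_radius_um=2.0, n_tracks=40, n_frames=12, seed=71)
        )
        flags = [classify_reversal(tr, roi, 0.0, 5.0) for tr in ts]
        oracle = []
        for tr in ts:
            sel = (tr.t > 0.0) & (tr.t <= 5.0)
            outside = [
                not (np.all(p >= [-3, -3, -3]) and np.all(p <= [3, 3, 3]))
                for p in tr.xyz[sel]
            ]
            oracle.append(any(outside))
        assert flags == oracle

    def test_all_inside_gives_zero_series(self):
        ts = TrackSet.from_tracks([make_track(np.zeros((5, 3)))])
        out = count_transmigrated(ts, SphereRoi((0, 0, 0), 10.0))
        assert np.all(out["count"] == 0)

    def test_single_crossing_steps_once(self):
        pos = np.zeros((8, 3))
        pos[5:, 0] = 20.0
        ts = TrackSet.from_tracks([make_track(pos)])
        out = count_transmigrated(ts, SphereRoi((0, 0, 0), 10.0))
        assert out["count"].tolist() == [0] * 5 + [1] * 3

    def test_radial_migrators_match_exit_time_histogram(self):
        """Cumulative transmigration equals the ground-truth exit-time cumsum."""
        ts, _ = generate_tracks(
            WalkParams(mode="directed", bias_target=None, bias_strength=1.0,
                       persistence=1.0, step_um=1.0, start_radius_um=3.0,
                       n_tracks=25, n_frames=20, seed=81)
        )
        boundary = SphereRoi((0, 0, 0), 8.0)
        out = count_transmigrated(ts, boundary)
        exits = []
        for tr in ts:
            d = np.linalg.norm(tr.xyz, axis=1)
            idx = np.flatnonzero(d > 8.0)
            if idx.size:
                exits.append(tr.t[idx[0]])
        times = out["t"].to_numpy()
        oracle = [(np.asarray(exits) <= t).sum() for t in times]
        assert out["count"].tolist() == oracle
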