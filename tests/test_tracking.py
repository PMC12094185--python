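"""Linking, speeds, MSD, diffusion fitting and motion classification."""

import numpy as np
import pandas as pd
import pytest

from satquant import synthgen, tracking
from satquant.core import InsufficientDataError


def spots_frame(rows):
    return pd.DataFrame(rows, columns=["FRAME", "POSITION_X", "POSITION_Y"]).assign(
        TRACK_ID=np.nan, INTENSITY=1.0, DIAMETER=0.3)


def make_traj(positions, dt_s=5.0, track_id=0, frames=None):
    positions = np.asarray(positions, float)
    if frames is None:
        frames = np.arange(len(positions))
    return tracking.Trajectory(track_id, frames, positions, dt_s=dt_s)


class TestLink:
    def test_single_stationary_spot_one_track(self):
        spots = spots_frame([(f, 1.0, 1.0) for f in range(20)])
        trajs = tracking.link(spots)
        assert len(trajs) == 1
        assert len(trajs[0]) == 20

    def test_distant_spots_stay_separate(self):
        rows = []
        for f in range(10):
            rows += [(f, 0.0, 0.0), (f, 12.0, 0.0)]  # 12 µm apart > 5 µm gate
        trajs = tracking.link(spots_frame(rows))
        assert len(trajs) == 2
        assert all(len(t) == 10 for t in trajs)

    def test_gap_closing_bridges_one_missing_frame(self):
        rows = [(f, 0.1 * f, 0.0) for f in range(10) if f != 4]
        trajs = tracking.link(spots_frame(rows))
        assert len(trajs) == 1
        assert list(trajs[0].frames) == [0, 1, 2, 3, 5, 6, 7, 8, 9]

    def test_gap_longer_than_limit_splits_track(self):
        rows = [(f, 0.0, 0.0) for f in range(10) if f not in (3, 4, 5)]
        trajs = tracking.link(spots_frame(rows), max_gap_frames=2)
        assert len(trajs) == 2

    def test_linking_conserves_spots(self):
        spots, _ = synthgen.make_tracks("normal", n_tracks=30, n_frames=20,
                                        D_um2_s=0.01, seed=60)
        trajs = tracking.link(spots)
        assert sum(len(t) for t in trajs) == len(spots)

    def test_recovers_generator_tracks_with_deletion(self):
        spots, truth = synthgen.make_tracks("normal", n_tracks=10, n_frames=30,
                                            D_um2_s=0.005, start_box_um=(100, 100),
                                            seed=61)
        # delete one detection per track to exercise gap closing
        drop = [tid * 30 + 7 for tid in range(10)]
        trimmed = spots.drop(index=drop).reset_index(drop=True)
        trajs = tracking.link(trimmed)
        assert len(trajs) == 10
        assert all(len(t) == 29 for t in trajs)


class TestSpeedsAndMsd:
    def test_stationary_track_zero_speeds(self):
        traj = make_traj([(1.0, 1.0)] * 10)
        assert np.allclose(tracking.instantaneous_speeds(traj), 0.0)

    def test_constant_drift_speed(self):
        pos = [(0.5 * 5.0 * f, 0.0) for f in range(10)]  # 0.5 µm/s at dt 5 s
        traj = make_traj(pos)
        assert np.allclose(tracking.instantaneous_speeds(traj), 0.5)

    def test_speed_matches_brute_force(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=1, n_frames=40,
                                        D_um2_s=0.01, seed=62)
        traj = synthgen.truth_trajectories(truth)[0]
        got = tracking.instantaneous_speeds(traj)
        steps = np.linalg.norm(np.diff(traj.positions_um, axis=0), axis=1)
        assert np.allclose(got, steps / 5.0, atol=1e-12)

    def test_msd_zero_for_stationary(self):
        curve = tracking.compute_msd(make_traj([(2.0, 3.0)] * 20))
        assert np.allclose(curve.msd_um2, 0.0)
        assert curve.msd_um2[0] == 0.0

    def test_ballistic_msd_quadratic_exact(self):
        v, dt = 0.3, 5.0
        pos = [(v * dt * f, 0.0) for f in range(20)]
        curve = tracking.compute_msd(make_traj(pos, dt_s=dt))
        assert np.allclose(curve.msd_um2, (v * curve.lag_s) ** 2, atol=1e-10)

    def test_n_pairs_decreasing(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=1, n_frames=30,
                                        D_um2_s=0.01, seed=63)
        curve = tracking.compute_msd(synthgen.truth_trajectories(truth)[0])
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_short_track_rejected(self):
        with pytest.raises(InsufficientDataError):
            tracking.compute_msd(make_traj([(0, 0), (1, 1)]))

    def test_msd_invariant_under_rigid_transform(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=1, n_frames=30,
                                        D_um2_s=0.01, seed=64)
        traj = synthgen.truth_trajectories(truth)[0]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = make_traj(traj.positions_um @ R.T + np.array([5.0, -3.0]))
        a = tracking.compute_msd(traj)
        b = tracking.compute_msd(moved)
        assert np.allclose(a.msd_um2, b.msd_um2, atol=1e-9)
        assert np.allclose(tracking.instantaneous_speeds(traj),
                           tracking.instantaneous_speeds(moved), atol=1e-9)


class TestEnsembleFit:
    def test_stationary_ensemble_zero_slope(self):
        trajs = [make_traj([(i, i)] * 15, track_id=i) for i in range(3)]
        _, fit = tracking.ensemble_weighted_msd(trajs)
        assert fit.D_um2_s == pytest.approx(0.0, abs=1e-12)

    def test_pure_drift_poor_linear_goodness(self):
        trajs = [make_traj([(0.5 * 5 * f, 0.0) for f in range(30)], track_id=i)
                 for i in range(3)]
        curve, fit = tracking.ensemble_weighted_msd(trajs)
        # quadratic MSD: the linear fit leaves clear structure
        lag, msd = curve.lag_s[1:], curve.msd_um2[1:]
        resid = msd - (fit.intercept_um2 + 4 * fit.D_um2_s * lag)
        assert np.max(np.abs(resid)) / msd.max() > 0.05

    def test_brownian_diffusion_recovered(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=200, n_frames=50,
                                        D_um2_s=0.01, dt_s=5.0, seed=65)
        _, fit = tracking.ensemble_weighted_msd(synthgen.truth_trajectories(truth))
        assert 0.009 <= fit.D_um2_s <= 0.011


class TestClassification:
    def test_noise_free_drift_is_directed(self):
        pos = [(0.5 * f, 0.1 * f) for f in range(30)]
        c = tracking.classify_track(make_traj(pos))
        assert c.final_class == "directed"

    def test_frozen_track_with_noise_not_normal(self):
        rng = np.random.default_rng(66)
        pos = np.zeros((30, 2)) + rng.normal(0, 0.02, (30, 2))
        c = tracking.classify_track(make_traj(pos))
        assert c.final_class in ("confined", "subdiffusive")

    def test_short_track_excluded(self):
        with pytest.raises(InsufficientDataError):
            tracking.classify_track(make_traj([(0, 0)] * 10))

    def test_order_independent_and_deterministic(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=10, n_frames=30,
                                        D_um2_s=0.01, seed=67)
        trajs = synthgen.truth_trajectories(truth)
        labels = {t.track_id: tracking.classify_track(t).final_class for t in trajs}
        labels_rev = {t.track_id: tracking.classify_track(t).final_class
                      for t in reversed(trajs)}
        assert labels == labels_rev

    @pytest.mark.parametrize("mode,kwargs", [
        ("normal", dict(D_um2_s=0.01)),
        ("subdiffusive", dict(D_um2_s=0.01, alpha=0.5)),
        ("confined", dict(D_um2_s=0.01, L_um=0.3)),
        ("directed", dict(D_um2_s=0.01, v_um_s=0.1)),
    ])
    def test_per_mode_recovery(self, mode, kwargs):
        _, truth = synthgen.make_tracks(mode, n_tracks=50, n_frames=50,
                                        dt_s=5.0, seed=68, **kwargs)
        hits = sum(tracking.classify_track(t).final_class == mode
                   for t in synthgen.truth_trajectories(truth))
        assert hits / 50 >= 0.8


class TestSummarizeFractions:
    def test_single_cell_all_normal(self):
        out = tracking.summarize_fractions({"cell": ["normal"] * 5})
        assert out.loc["normal", "mean_fraction"] == 1.0
        assert out.mean_fraction.sum() == pytest.approx(1.0)

    def test_two_cells_averaged(self):
        out = tracking.summarize_fractions({
            "c1": ["normal"] * 4, "c2": ["directed"] * 6})
        assert out.loc["normal", "mean_fraction"] == pytest.approx(0.5)
        assert out.loc["directed", "mean_fraction"] == pytest.approx(0.5)
        assert out.loc["subdiffusive", "mean_fraction"] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(69)
        cells = {f"c{i}": list(rng.choice(tracking.MOTION_CLASSES, rng.integers(3, 20)))
                 for i in range(6)}
        out = tracking.summarize_fractions(cells)
        for cls in tracking.MOTION_CLASSES:
            fracs = [v.count(cls) / len(v) for v in cells.values()]
            assert out.loc[cls, "mean_fraction"] == pytest.approx(np.mean(fracs), abs=1e-12)
            assert out.loc[cls, "sem"] == pytest.approx(
                np.std(fracs, ddof=1) / np.sqrt(len(fracs)), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            tracking.summarize_fractions({})
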