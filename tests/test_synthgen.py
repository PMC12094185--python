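"""Generator correctness: determinism, closed-form statistics, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satquant import synthgen, tracking, orthomap
from satquant.core import InvalidParameterError


class TestPunctaImage:
    def test_empty_case_is_constant_zero(self):
        img, truth = synthgen.make_puncta_image(n_foci=0, noise_sd=0.0, seed=0)
        assert np.all(img.values == 0)
        assert len(truth.records) == 0

    def test_deterministic_for_fixed_seed(self):
        a, ta = synthgen.make_puncta_image(n_foci=50, seed=1)
        b, tb = synthgen.make_puncta_image(n_foci=50, seed=1)
        assert np.array_equal(a.values, b.values)
        assert ta.records.equals(tb.records)

    def test_different_seed_differs(self):
        a, _ = synthgen.make_puncta_image(n_foci=50, seed=1)
        b, _ = synthgen.make_puncta_image(n_foci=50, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_radial_enrichment_matches_sampling_density(self):
        # spatial density ∝ exp(-r/λ) ⇒ radii ~ Gamma(shape=2, scale=λ)
        center = (40.0, 40.0)
        img, truth = synthgen.make_puncta_image(
            n_foci=2000, image_size_um=(80, 80), centers_um=[center],
            radial_enrichment_um=1.0, noise_sd=0.0, seed=3)
        r = np.hypot(truth.records.x_um - center[0], truth.records.y_um - center[1])
        p = stats.kstest(r, stats.gamma(a=2, scale=1.0).cdf).pvalue
        assert p > 0.01

    def test_spots_land_inside_image(self):
        img, truth = synthgen.make_puncta_image(
            n_foci=500, image_size_um=(10, 10), centers_um=[(9.5, 9.5)],
            radial_enrichment_um=2.0, seed=4)
        assert truth.records.x_um.between(0, 10).all()
        assert truth.records.y_um.between(0, 10).all()

    @pytest.mark.parametrize("bad", [
        dict(n_foci=-1), dict(n_foci=5, pixel_size_um=0.0),
        dict(n_foci=5, psf_sigma_um=-1.0),
        dict(n_foci=5, radial_enrichment_um=1.0),  # no centers
    ])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            synthgen.make_puncta_image(**bad)


class TestColocPair:
    def test_full_overlap_same_positions(self):
        (a, b), truth = synthgen.make_coloc_pair(
            n_foci=30, shared_fraction=1.0, jitter_um=0.0, noise_sd=0.0, seed=5)
        rec = truth.records
        assert rec.shared.all()
        assert np.allclose(rec.a_x_um, rec.b_x_um)
        assert np.allclose(rec.a_y_um, rec.b_y_um)
        # identical up to per-spot amplitudes: same support
        assert ((a.values > 0) == (b.values > 0)).mean() > 0.99

    def test_zero_fraction_independent(self):
        _, truth = synthgen.make_coloc_pair(
            n_foci=40, shared_fraction=0.0, noise_sd=0.0, seed=6)
        assert not truth.records.shared.any()
        assert not np.allclose(truth.records.a_x_um, truth.records.b_x_um)

    def test_floor_rounding_of_shared_count(self):
        _, truth = synthgen.make_coloc_pair(n_foci=60, shared_fraction=0.8, seed=7)
        assert int(truth.records.shared.sum()) == 48  # floor(60 * 0.8)

    def test_fraction_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            synthgen.make_coloc_pair(n_foci=10, shared_fraction=1.2)


class TestTracks:
    def test_frozen_particle(self):
        spots, _ = synthgen.make_tracks("normal", n_tracks=3, n_frames=10,
                                        D_um2_s=0.0, seed=8)
        for _, grp in spots.groupby(spots.index // 10):
            assert grp.POSITION_X.nunique() == 1

    def test_pure_drift_step_length(self):
        _, truth = synthgen.make_tracks("directed", n_tracks=5, n_frames=10,
                                        D_um2_s=0.0, v_um_s=0.5, dt_s=5.0, seed=9)
        for t in synthgen.truth_trajectories(truth):
            steps = np.linalg.norm(np.diff(t.positions_um, axis=0), axis=1)
            assert np.allclose(steps, 2.5)

    def test_brownian_mean_squared_step(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=200, n_frames=50,
                                        D_um2_s=0.01, dt_s=5.0, seed=10)
        sq = []
        for t in synthgen.truth_trajectories(truth):
            sq.append(np.sum(np.diff(t.positions_um, axis=0) ** 2, axis=1))
        mean_sq = float(np.concatenate(sq).mean())
        assert abs(mean_sq - 0.2) / 0.2 < 0.05  # 4·D·dt = 0.2 µm²

    def test_brownian_steps_normal_with_stated_variance(self):
        _, truth = synthgen.make_tracks("normal", n_tracks=250, n_frames=41,
                                        D_um2_s=0.01, dt_s=5.0, seed=11)
        steps = np.concatenate([np.diff(t.positions_um, axis=0)
                                for t in synthgen.truth_trajectories(truth)])
        assert abs(steps.ravel().var() - 0.1) / 0.1 < 0.05
        assert stats.normaltest(steps[:, 0]).pvalue > 0.01

    @pytest.mark.parametrize("alpha", [0.4, 0.7])
    def test_fbm_exponent_recovery(self, alpha):
        _, truth = synthgen.make_tracks("subdiffusive", n_tracks=100, n_frames=60,
                                        D_um2_s=0.01, alpha=alpha, dt_s=5.0, seed=12)
        trajs = synthgen.truth_trajectories(truth)
        curve, _ = tracking.ensemble_weighted_msd(trajs)
        est = tracking.fit_alpha(curve, max_lag=10)
        assert abs(est - alpha) < 0.1

    def test_confined_never_leaves_disc_and_plateaus(self):
        L = 0.3
        _, truth = synthgen.make_tracks("confined", n_tracks=50, n_frames=80,
                                        D_um2_s=0.01, L_um=L, dt_s=5.0, seed=13)
        long_msd = []
        for t in synthgen.truth_trajectories(truth):
            r = np.linalg.norm(t.positions_um - t.positions_um[0], axis=1)
            assert np.all(r <= L + 1e-9)
            long_msd.append(tracking.compute_msd(t).msd_um2[-1])
        assert np.mean(long_msd) < 2 * L**2

    def test_missing_mode_parameter(self):
        with pytest.raises(InvalidParameterError):
            synthgen.make_tracks("confined", D_um2_s=0.01)  # no L_um
        with pytest.raises(InvalidParameterError):
            synthgen.make_tracks("directed", D_um2_s=0.01)  # no v_um_s

    def test_determinism(self):
        a, _ = synthgen.make_tracks("normal", n_tracks=5, n_frames=10,
                                    D_um2_s=0.01, seed=1)
        b, _ = synthgen.make_tracks("normal", n_tracks=5, n_frames=10,
                                    D_um2_s=0.01, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestLfq:
    def test_no_missing_when_rate_zero(self):
        matrix, *_ = synthgen.make_lfq(n_proteins=200, missing_rate=0.0, seed=14)
        assert matrix.notna().all().all()

    def test_null_groups_balanced(self):
        matrix, groups, _, _ = synthgen.make_lfq(
            n_proteins=2000, n_enriched=0, sd_log2=0.5, seed=15)
        bait = [s for s, g in groups.items() if g == "bait"]
        ctrl = [s for s, g in groups.items() if g == "control"]
        diff = matrix[bait].mean().mean() - matrix[ctrl].mean().mean()
        assert abs(diff) < 0.05  # sampling error only

    def test_censoring_deletes_low_values(self):
        matrix, _, _, truth = synthgen.make_lfq(
            n_proteins=500, missing_rate=0.3, censor_strength=3.0, seed=16)
        observed_mean = float(np.nanmean(matrix.to_numpy()))
        deleted_mean = float(truth.censored_values.true_value.mean())
        assert observed_mean > deleted_mean

    def test_realized_missing_rate_near_target(self):
        matrix, *_ = synthgen.make_lfq(n_proteins=1000, missing_rate=0.2,
                                       censor_strength=3.0, seed=17)
        rate = float(matrix.isna().mean().mean())
        assert abs(rate - 0.2) < 0.03

    def test_tsv_round_trip(self, tmp_path):
        from satquant import lfq as lfqmod
        matrix, groups, meta, _ = synthgen.make_lfq(
            n_proteins=50, missing_rate=0.2, seed=18)
        path = tmp_path / "lfq.tsv"
        synthgen.write_lfq_tsv(path, matrix, meta)
        loaded = lfqmod.load_lfq(path, groups)
        pd.testing.assert_frame_equal(loaded.data, matrix, check_exact=False,
                                      atol=1e-9)
        assert loaded.meta.Peptides.equals(meta.Peptides)


class TestHits:
    def test_zero_fraction_empty_truth(self):
        _, _, truth = synthgen.make_hits(n_a=20, n_b=20, ortholog_fraction=0.0, seed=19)
        assert len(truth.records) == 0

    def test_perfect_case_all_pairs(self):
        fwd, rev, truth = synthgen.make_hits(n_a=15, n_b=15, ortholog_fraction=1.0,
                                             decoy_hits_per_gene=0, seed=20)
        m = orthomap.reciprocal_best(fwd, rev)
        assert len(m) == 15
        assert set(m.pairs) == set(map(tuple, truth.records.to_numpy()))

    def test_mixed_table_bbh_equals_planted(self):
        fwd, rev, truth = synthgen.make_hits(n_a=60, n_b=80, ortholog_fraction=0.5,
                                             decoy_hits_per_gene=3, seed=21)
        m = orthomap.reciprocal_best(fwd, rev)
        assert set(m.pairs) == set(map(tuple, truth.records.to_numpy()))


def test_ground_truth_json_round_trip():
    _, truth = synthgen.make_puncta_image(n_foci=5, seed=22)
    back = synthgen.GroundTruth.from_json(truth.to_json())
    assert back.kind == truth.kind
    assert back.parameters == truth.parameters
    assert np.allclose(back.records.x_um, truth.records.x_um)
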