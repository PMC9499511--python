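"""Diffusion-state HMM: fitting, coarse-graining, dwell/flux, decoding."""

import numpy as np
import pytest

from srptrack.hmm import (
    CoarseModel,
    HMMModel,
    bootstrap_uncertainty,
    coarse_grain,
    decode,
    dwell_and_flux,
    fit_hmm,
    sweep_models,
)
from srptrack.simulate import markov_switching_tracks, wildtype_rate_matrix
from srptrack.tracks import Track, total_steps

from conftest import WT_D, WT_DWELL_BOUND, WT_DWELL_FREE, WT_OCC


class TestFit:
    def test_single_state_D_recovery_within_3_percent(self):
        tracks = markov_switching_tracks(
            [1.0], mean_dwells=[1e9], n_tracks=1700, mean_track_len=30,
            loc_error=0.03, seed=10,
        )
        assert total_steps(tracks) >= 45_000
        m = fit_hmm(tracks, K=1, n_restarts=2, seed=0)
        assert m.D[0] == pytest.approx(1.0, rel=0.03)

    def test_three_state_occupancy_and_D_recovery(self, wildtype_fit):
        """Wild-type three-state data (>=40k steps): occupancies within
        ±0.04 and D within ±10% of the generator's ground truth."""
        model, _ = wildtype_fit
        assert model.n_steps >= 40_000
        for k in range(3):
            assert abs(model.pi[k] - WT_OCC[k]) < 0.04
            assert model.D[k] == pytest.approx(WT_D[k], rel=0.10)

    def test_em_loglik_monotone(self, wildtype_fit):
        model, _ = wildtype_fit
        ll = np.array(model.ll_history)
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_init_label_permutation_invariant(self):
        """Permuting the initialization's state labels leaves the converged
        likelihood unchanged."""
        tracks = markov_switching_tracks(
            [0.1, 2.0], mean_dwells=[1.0, 1.0], n_tracks=300, loc_error=0.02,
            seed=11,
        )
        m1 = fit_hmm(tracks, K=2, n_restarts=1, init_D=[0.05, 1.0], seed=0)
        m2 = fit_hmm(tracks, K=2, n_restarts=1, init_D=[1.0, 0.05], seed=0)
        assert m1.log_likelihood == pytest.approx(m2.log_likelihood, rel=1e-6)
        assert np.allclose(m1.D, m2.D, rtol=1e-3)

    def test_blur_correction_changes_emission_variance(self):
        """With a finite exposure the same data fit at the same D implies a
        slightly larger D estimate (the blur factor shrinks the diffusive
        variance per step)."""
        tracks = markov_switching_tracks(
            [1.0], mean_dwells=[1e9], n_tracks=500, loc_error=0.0, seed=12,
        )
        m0 = fit_hmm(tracks, K=1, n_restarts=1, exposure=0.0, seed=0)
        m1 = fit_hmm(tracks, K=1, n_restarts=1, exposure=0.0015, seed=0)
        assert m1.D[0] > m0.D[0]
        assert m1.D[0] / m0.D[0] == pytest.approx(1 / (1 - 0.0015 / (3 * 0.02)),
                                                  rel=1e-3)

    def test_gap_steps_handled(self):
        """Tracks with single-frame gaps fit without error and recover D."""
        rng = np.random.default_rng(13)
        tracks = []
        for tid in range(400):
            n = 12
            frames = np.arange(n)
            # knock out one interior frame
            drop = rng.integers(2, n - 2)
            keep = frames != drop
            pos = np.cumsum(rng.normal(0, np.sqrt(2 * 1.0 * 0.02), (n, 2)), axis=0)
            tracks.append(Track(tid, 0, frames[keep], pos[keep],
                                np.full(keep.sum(), 0.02)))
        m = fit_hmm(tracks, K=1, n_restarts=1, seed=0)
        assert m.D[0] == pytest.approx(1.0, rel=0.08)

    def test_warns_on_too_few_steps(self):
        tracks = markov_switching_tracks([1.0], mean_dwells=[1e9], n_tracks=5,
                                         mean_track_len=5, seed=1)
        with pytest.warns(UserWarning, match="steps"):
            fit_hmm(tracks, K=2, n_restarts=1, max_iter=10, seed=0)


class TestSweep:
    @pytest.fixture(scope="class")
    def sweep(self):
        tracks = markov_switching_tracks(
            WT_D, rate_matrix=wildtype_rate_matrix(WT_OCC, WT_DWELL_BOUND,
                                                   WT_DWELL_FREE),
            n_tracks=350, mean_track_len=30, loc_error=0.03, seed=21,
        )
        return sweep_models(tracks, K_range=range(3, 9), n_restarts=3, seed=5)

    def test_likelihood_non_decreasing_in_K(self, sweep):
        lls = [m.log_likelihood for m in sweep]
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_fitted_D_cluster_containment(self, sweep):
        """Models K=4..8 place every non-negligible fitted D inside one of
        the three ground-truth clusters.

        The intermediate and fast clusters are the truth ±50%; the slow
        cluster extends down to zero because at D ~ 0.05 µm²/s the 30 nm
        localization noise dominates the displacement variance, so splits
        of the slow state can land anywhere below it (the same reason the
        observed slow cluster spans down to ~0.003 µm²/s)."""
        clusters = [(0.0, 1.5 * WT_D[0]), (0.5 * WT_D[1], 1.5 * WT_D[1]),
                    (0.5 * WT_D[2], 1.5 * WT_D[2])]
        for m in sweep[1:]:
            for d, p in zip(m.D, m.pi):
                if p < 0.02:
                    continue  # numerically empty duplicate state
                assert any(lo <= d <= hi for lo, hi in clusters), (m.K, m.D)

    def test_coarse_occupancies_stable_across_model_size(self, sweep):
        """Coarse-grained occupancies from K=8 match K=3 within ±0.05."""
        c3 = coarse_grain(sweep[0]).pi_coarse
        c8 = coarse_grain(sweep[-1]).pi_coarse
        assert np.all(np.abs(c3 - c8) < 0.05)


class TestCoarseGrain:
    def _model(self, D, pi, A, dt=0.02):
        return HMMModel(K=len(D), D=np.array(D), pi=np.array(pi),
                        A=np.array(A), frame_dt=dt, exposure=0.0,
                        log_likelihood=0.0, startprob=np.array(pi))

    def test_weighted_average_arithmetic(self):
        """Fine states D=(0.04, 0.06), pi=(0.1, 0.2) merge to
        D = 0.0533, pi = 0.3."""
        m = self._model([0.04, 0.06, 2.0], [0.1, 0.2, 0.7],
                        [[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        c = coarse_grain(m)
        assert c.pi_coarse[0] == pytest.approx(0.3)
        assert c.D_coarse[0] == pytest.approx((0.1 * 0.04 + 0.2 * 0.06) / 0.3)
        assert c.pi_coarse.sum() == pytest.approx(1.0)

    def test_identity_when_states_already_split(self):
        A = [[0.98, 0.01, 0.01], [0.02, 0.96, 0.02], [0.01, 0.04, 0.95]]
        m = self._model([0.05, 1.7, 4.3], [0.29, 0.55, 0.16], A)
        c = coarse_grain(m)
        assert np.allclose(c.D_coarse, m.D)
        assert np.allclose(c.pi_coarse, m.pi)
        assert np.allclose(c.A_coarse, m.A)

    def test_dwell_diagonal_relation(self):
        """Dwell 1.9 s at 20 ms frames corresponds to a coarse diagonal of
        1 - 0.02/1.9 = 0.98947."""
        A = [[0.98947368, 0.01052632], [0.02, 0.98]]
        m = self._model([1.7, 0.05], [0.6, 0.4], A)
        c = coarse_grain(m)
        # D=1.7 is group 1 (intermediate), D=0.05 group 0
        assert c.dwell[1] == pytest.approx(1.9, rel=1e-6)
        assert c.dwell[0] == pytest.approx(1.0, rel=1e-6)

    def test_threshold_tie_joins_lower_group(self):
        m = self._model([0.8, 3.0], [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]])
        c = coarse_grain(m)
        assert c.group_map.tolist() == [0, 1]

    def test_empty_group_marked(self):
        m = self._model([0.05, 4.3], [0.4, 0.6], [[0.95, 0.05], [0.05, 0.95]])
        c = coarse_grain(m)
        assert c.pi_coarse[1] == 0.0
        assert np.isnan(c.D_coarse[1])
        assert np.isnan(c.dwell[1])

    def test_rejects_nonincreasing_thresholds(self):
        m = self._model([0.05], [1.0], [[1.0]])
        with pytest.raises(ValueError):
            coarse_grain(m, thresholds=(3.0, 0.8))


class TestDwellFlux:
    def test_stationary_two_state_balance_exact(self):
        A = np.array([[0.98, 0.02], [0.01, 0.99]])
        w, v = np.linalg.eig(A.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi /= pi.sum()
        m = HMMModel(K=2, D=np.array([0.05, 1.7]), pi=pi, A=A, frame_dt=0.02,
                     exposure=0.0, log_likelihood=0.0, startprob=pi)
        fl = dwell_and_flux(coarse_grain(m))
        assert np.allclose(fl["flux_in"], fl["flux_out"])
        occupied = fl["flux_out"] > 0
        assert np.allclose(fl["balance_ratio"][occupied], 1.0)

    def test_dwell_formula(self):
        A = np.array([[0.98, 0.02], [0.02, 0.98]])
        m = HMMModel(K=2, D=np.array([0.05, 1.7]), pi=np.array([0.5, 0.5]),
                     A=A, frame_dt=0.02, exposure=0.0, log_likelihood=0.0,
                     startprob=np.array([0.5, 0.5]))
        fl = dwell_and_flux(coarse_grain(m))
        assert fl["dwell_s"][0] == pytest.approx(1.0)

    def test_infinite_dwell_reported(self):
        A = np.array([[1.0, 0.0], [0.02, 0.98]])
        m = HMMModel(K=2, D=np.array([0.05, 1.7]), pi=np.array([0.5, 0.5]),
                     A=A, frame_dt=0.02, exposure=0.0, log_likelihood=0.0,
                     startprob=np.array([0.5, 0.5]))
        c = coarse_grain(m)
        assert np.isinf(c.dwell[0])


class TestDecode:
    def test_single_state_data_confident(self):
        tracks = markov_switching_tracks([1.0], mean_dwells=[1e9], n_tracks=40,
                                         loc_error=0.02, seed=30)
        m = fit_hmm(tracks, K=1, n_restarts=1, seed=0)
        paths = decode(tracks, m)
        for p in paths:
            assert (p.states == 0).all()
            assert (p.posteriors.max(axis=1) > 0.99).all()

    def test_posteriors_sum_to_one(self, wildtype_tracks, wildtype_fit):
        _, coarse = wildtype_fit
        paths = decode(wildtype_tracks[:50], coarse)
        for p in paths:
            assert np.allclose(p.posteriors.sum(axis=1), 1.0)

    def test_switch_times_within_two_frames(self):
        """Viterbi finds >=80% of switches between well-separated states
        within ±2 frames of the true switch."""
        tracks = markov_switching_tracks(
            [0.05, 2.5], mean_dwells=[1.0, 1.0], n_tracks=400,
            mean_track_len=40, loc_error=0.02, seed=31,
        )
        m = fit_hmm(tracks, K=2, n_restarts=2, seed=0)
        paths = decode(tracks, m)
        hits = misses = 0
        for t, p in zip(tracks, paths):
            true_sw = np.flatnonzero(np.diff(t.true_states) != 0) + 1
            est_sw = np.flatnonzero(np.diff(p.states) != 0) + 1
            for s in true_sw:
                if len(est_sw) and np.min(np.abs(est_sw - s)) <= 2:
                    hits += 1
                else:
                    misses += 1
        assert hits / (hits + misses) >= 0.80

    def test_ambiguous_positions_flagged(self, wildtype_tracks, wildtype_fit):
        _, coarse = wildtype_fit
        paths = decode(wildtype_tracks[:200], coarse, posterior_threshold=0.95)
        amb = np.concatenate([p.ambiguous for p in paths])
        post = np.vstack([p.posteriors for p in paths])
        assert (post.max(axis=1)[amb] <= 0.95).all()
        assert (post.max(axis=1)[~amb] > 0.95).all()


class TestBootstrap:
    @pytest.fixture(scope="class")
    def small_tracks(self):
        return markov_switching_tracks(
            [0.05, 1.7], mean_dwells=[1.0, 1.9], n_tracks=300,
            mean_track_len=20, loc_error=0.03, seed=40,
        )

    def test_single_resample_collapses_to_point(self, small_tracks):
        res = bootstrap_uncertainty(small_tracks, K=2, n_boot=1, seed=1)
        ci = res["pi_coarse_ci"]
        assert np.allclose(ci[0], ci[1])

    def test_ci_width_scales_with_dataset_size(self):
        """CI width shrinks roughly as 1/sqrt(n) across a 4x size change
        (within a factor of 1.5)."""
        widths = []
        for n_tracks, seed in ((150, 50), (600, 51)):
            tracks = markov_switching_tracks(
                [1.0], mean_dwells=[1e9], n_tracks=n_tracks, mean_track_len=10,
                loc_error=0.02, seed=seed,
            )
            res = bootstrap_uncertainty(tracks, K=1, n_boot=80, seed=7,
                                        max_iter=50)
            lo, hi = res["D_coarse_ci"][0], res["D_coarse_ci"][1]
            g = 1  # D = 1 µm²/s falls in the intermediate coarse group
            widths.append(float(hi[g] - lo[g]))
        ratio = widths[0] / widths[1]
        assert 2.0 / 1.5 < ratio < 2.0 * 1.5
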