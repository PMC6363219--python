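"""Reversible MSM estimation, discrete TRAM, timescales, bootstrap."""

import numpy as np
import pytest

from memmpath.constants import KBT_310
from memmpath.discretize import DiscreteTrajectories, MicrostateMap
from memmpath.msm import count_matrix, largest_connected_set, reversible_mle
from memmpath.tram import (bootstrap_resample, estimate_tram,
                           free_energy_profile, implied_timescales,
                           implied_timescales_ladder, median_quartiles)
from memmpath.simulate import EnsembleSpec, Trajectory, TrajectoryEnsemble


def _discrete(dtrajs, ens_ids, bias, n_states, n_clusters=1):
    n_z = n_states // n_clusters
    smap = MicrostateMap(z_edges=np.arange(n_z + 1, dtype=float),
                         cluster_centers=np.zeros((n_clusters, 1)))
    slices, at = [], 0
    for d in dtrajs:
        slices.append(slice(at, at + len(d)))
        at += len(d)
    return DiscreteTrajectories(dtrajs=dtrajs, ensemble_ids=ens_ids,
                                bias=bias, traj_slices=slices, map=smap)


class TestReversibleMle:
    def test_detailed_balance_and_row_sums(self, chain_sampler):
        rng = np.random.default_rng(0)
        T_true = rng.random((4, 4)) + 2 * np.eye(4)
        T_true /= T_true.sum(1, keepdims=True)
        d = chain_sampler(T_true, 20_000, seed=1)
        C = count_matrix([d], 1, 4)
        T, pi = reversible_mle(C, tol=1e-14)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        flux = pi[:, None] * T
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_connected_set(self):
        C = np.zeros((4, 4))
        C[0, 1] = C[1, 0] = 5
        C[2, 3] = C[3, 2] = 1
        lcc = largest_connected_set(C)
        assert lcc.tolist() == [0, 1]


class TestTramFixedPoints:
    def test_symmetric_two_state_counts(self):
        # two mirror-image trajectories give exactly symmetric self and
        # cross counts: the stationary split must be even
        d1 = np.array([0, 0, 1, 1] * 100 + [0])
        d2 = 1 - d1
        n = len(d1)
        data = _discrete([d1, d2], [0, 0], np.zeros((1, 2 * n)), 2)
        memm = estimate_tram(data, lag=1, tol=1e-13, max_iter=100_000)
        assert np.allclose(memm.pi, [0.5, 0.5], atol=1e-9)

    def test_single_ensemble_reduces_to_reversible_mle(self, chain_sampler):
        rng = np.random.default_rng(3)
        T_true = rng.random((4, 4)) + np.eye(4)
        T_true /= T_true.sum(1, keepdims=True)
        d = chain_sampler(T_true, 20_000, seed=5)
        data = _discrete([d], [0], np.zeros((1, len(d))), 4)
        memm = estimate_tram(data, lag=1, tol=1e-14, max_iter=300_000)
        C = count_matrix([d], 1, 4)
        T_mle, pi_mle = reversible_mle(C, tol=1e-15)
        assert np.max(np.abs(memm.T - T_mle)) < 1e-8
        assert np.max(np.abs(memm.pi - pi_mle)) < 1e-8

    def test_three_state_chain_recovers_stationary(self, chain_sampler):
        # reversible 3-state chain with known Boltzmann weights
        pi_true = np.array([0.5, 0.2, 0.3])
        T_true = np.array([[0.8, 0.12, 0.08],
                           [0.3, 0.55, 0.15],
                           [2.0 / 15, 0.1, 0.7667]])
        T_true[2, 2] = 1 - T_true[2, :2].sum()
        flux = pi_true[:, None] * T_true
        assert np.allclose(flux, flux.T, atol=1e-3)
        d = chain_sampler(T_true, 50_000, seed=6)
        data = _discrete([d], [0], np.zeros((1, len(d))), 3)
        memm = estimate_tram(data, lag=1, tol=1e-12, max_iter=200_000)
        se = np.sqrt(pi_true * (1 - pi_true) / (50_000 / 10))
        assert np.all(np.abs(memm.pi - pi_true) < 3 * se)

    def test_detailed_balance_of_returned_matrix(self, small_memm):
        flux = small_memm.pi[:, None] * small_memm.T
        assert np.max(np.abs(flux - flux.T)) < 1e-10
        assert np.allclose(small_memm.T.sum(axis=1), 1.0, atol=1e-12)
        # G is the log of pi up to the anchoring constant
        g = -small_memm.kBT * np.log(small_memm.pi)
        assert np.allclose(small_memm.G, g - g.min(), atol=1e-8)

    def test_log_likelihood_monotone_single_ensemble(self, chain_sampler):
        rng = np.random.default_rng(11)
        T_true = rng.random((3, 3)) + np.eye(3)
        T_true /= T_true.sum(1, keepdims=True)
        d = chain_sampler(T_true, 10_000, seed=12)
        data = _discrete([d], [0], np.zeros((1, len(d))), 3)
        memm = estimate_tram(data, lag=1, tol=1e-13, max_iter=100_000,
                             ll_every=1)
        ll = memm.log_likelihood_trace
        assert np.all(np.diff(ll) >= -1e-8)

    def test_log_likelihood_increases_to_convergence(self, small_memm):
        # the coupled multiplier/free-energy update can show small transient
        # dips on multi-ensemble data; the likelihood must still increase
        # overall and end at its maximum
        ll = small_memm.log_likelihood_trace
        assert len(ll) > 2
        assert ll[-1] > ll[0]
        assert ll[-1] >= ll.max() - 5e-5 * abs(ll.max())

    def test_biased_plus_unbiased_beats_unbiased_alone(self, small_discrete,
                                                       small_memm, twowell):
        # umbrella + unbiased TRAM must track the analytic profile of the
        # generating landscape on well-sampled bins
        from memmpath.landscape import ground_truth_profile
        prof = free_energy_profile(small_memm)
        gt = ground_truth_profile(twowell, bins=400)
        g_true = np.interp(prof.z_centers, gt.z_centers, gt.profile)
        counts = small_discrete.microstate_counts().reshape(
            small_discrete.map.n_zbins, -1).sum(1)
        sel = np.isfinite(prof.G) & (counts >= 200)
        d = prof.G[sel] - g_true[sel]
        d -= d.mean()
        rms = float(np.sqrt((d**2).mean()))
        assert rms < 0.8  # small fixture; the acceptance run checks 0.3


class TestEqOneProfile:
    def _memm_with_G(self, G, n_clusters, kBT=KBT_310):
        n_z = len(G) // n_clusters
        smap = MicrostateMap(z_edges=np.arange(n_z + 1, dtype=float),
                             cluster_centers=np.zeros((n_clusters, 1)))
        from memmpath.tram import MEMM
        active = np.flatnonzero(np.isfinite(G))
        g = np.asarray(G, float)[active]
        pi = np.exp(-g / kBT)
        pi /= pi.sum()
        return MEMM(lag_frames=1, lag_ns=1.0, active_set=active, pi=pi,
                    G=g - g.min(), T=np.eye(len(active)),
                    biased_f=np.zeros((1, len(active))),
                    ensemble_shifts=np.zeros(1), map=smap, kBT=kBT,
                    unbiased_index=0, converged=True, n_iter=1,
                    log_likelihood_trace=np.zeros(1))

    def test_single_cluster_profile_is_microstate_energy(self):
        G = np.array([0.0, 1.0, 2.5, 0.3])
        memm = self._memm_with_G(G, n_clusters=1)
        prof = free_energy_profile(memm)
        assert np.allclose(prof.G, G, atol=1e-10)

    def test_two_equal_clusters_gain_ln2(self):
        # two clusters at Gbar = 0 in one z bin vs one populated cluster in
        # the other: the doubled bin is lower by kBT ln 2 = 0.427 kcal/mol
        G = np.array([0.0, 0.0, 0.0, np.inf])
        memm = self._memm_with_G(G, n_clusters=2)
        prof = free_energy_profile(memm)
        assert prof.G[0] == pytest.approx(0.0)
        assert prof.G[1] - prof.G[0] == pytest.approx(
            KBT_310 * np.log(2.0), abs=1e-10)

    def test_empty_cluster_contributes_nothing(self):
        G = np.array([0.0, np.inf])
        memm = self._memm_with_G(G, n_clusters=2)
        prof = free_energy_profile(memm)
        assert prof.G[0] == 0.0

    def test_invariant_under_constant_shift(self):
        G = np.array([0.0, 1.0, 0.5, 2.0])
        a = free_energy_profile(self._memm_with_G(G, n_clusters=2)).G
        b = free_energy_profile(self._memm_with_G(G + 7.3, n_clusters=2)).G
        assert np.allclose(a, b, atol=1e-10)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # eigenvalue 0.8 at lag 0.4 ns -> t = -0.4/ln 0.8 = 1.7926 ns
        p = 0.1
        T = np.array([[1 - p, p], [p, 1 - p]])  # eigenvalue 1 - 2p = 0.8
        ts = implied_timescales(T, lag_ns=0.4, n=1)
        assert ts[0] == pytest.approx(-0.4 / np.log(0.8), abs=1e-12)
        assert ts[0] == pytest.approx(1.7926, abs=1e-4)

    def test_unit_eigenvalue_reports_infinity(self):
        T = np.eye(3)
        ts = implied_timescales(T, lag_ns=0.4, n=2)
        assert np.all(np.isinf(ts))

    def test_nonreversible_input_raises(self):
        T = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="reversible"):
            implied_timescales(T, lag_ns=0.4)

    def test_ladder_includes_default_tram_lag(self, chain_sampler):
        # slow two-state chain: relaxation ~200 steps, resolvable at every
        # ladder lag; implied timescales must be flat for a Markov chain
        T_true = np.array([[0.995, 0.005], [0.005, 0.995]])
        d = chain_sampler(T_true, 100_000, seed=8)
        lags = [50, 100, 200]
        out = implied_timescales_ladder([d], 2, lags, dt_ns=0.002)
        assert 200 in out
        vals = np.array([out[lag][0] for lag in lags])
        assert np.all(np.abs(vals / vals[0] - 1) < 0.3)


class TestBootstrap:
    def _ensemble(self, n_traj=4, frames=100):
        specs = {0: EnsembleSpec("umbrella", z0=0.0, k_bias=1.0,
                                 ensemble_id=0),
                 1: EnsembleSpec("unbiased", ensemble_id=1)}
        trajs = [Trajectory(z=np.zeros(frames), c=np.zeros(frames), dt=0.1,
                            ensemble_id=1, seed=i) for i in range(n_traj)]
        trajs.append(Trajectory(z=np.zeros(frames), c=np.zeros(frames),
                                dt=0.1, ensemble_id=0, seed=99))
        return TrajectoryEnsemble(trajs, specs)

    def test_single_trajectory_full_fraction_is_identity(self):
        ens = self._ensemble(n_traj=1)
        samples = bootstrap_resample(ens, n_samples=3, frac=1.0, seed=0)
        for s in samples:
            unb = [t for t in s if s.specs[t.ensemble_id].kind == "unbiased"]
            assert len(unb) == 1
            assert unb[0] is ens.trajectories[0]

    def test_default_fraction_reached_and_umbrella_kept(self):
        ens = self._ensemble()
        samples = bootstrap_resample(ens, n_samples=12, frac=0.9, seed=1)
        assert len(samples) == 12
        total = 400
        for s in samples:
            unb = [t for t in s if s.specs[t.ensemble_id].kind == "unbiased"]
            umb = [t for t in s if s.specs[t.ensemble_id].kind == "umbrella"]
            assert sum(len(t) for t in unb) >= 0.9 * total
            assert len(umb) == 1

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_resample(self._ensemble(), frac=1.5)

    def test_median_and_quartiles_of_1_to_13(self):
        med, q1, q3 = median_quartiles(np.arange(1, 14))
        assert (med, q1, q3) == (7.0, 4.0, 10.0)
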