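"""Brownian-dynamics generator: determinism, equilibrium laws, I/O."""

import numpy as np
import pytest
from scipy import stats

from memmpath.landscape import (Landscape, build_landscape, ground_truth_profile,
                                two_well_landscape)
from memmpath.simulate import (EnsembleSpec, emit_features, read_trajectories,
                               simulate_batch, simulate_trajectory,
                               simulate_umbrella_campaign, window_ladder,
                               write_trajectories)


UNBIASED = EnsembleSpec("unbiased", ensemble_id=0)


class TestDeterminism:
    def test_identical_seed_bit_identical(self, flat_landscape):
        a = simulate_trajectory(flat_landscape, UNBIASED, 2000, 1e-3, seed=42)
        b = simulate_trajectory(flat_landscape, UNBIASED, 2000, 1e-3, seed=42)
        assert np.array_equal(a.trajectories[0].z, b.trajectories[0].z)
        assert np.array_equal(a.trajectories[0].c, b.trajectories[0].c)

    def test_batch_matches_single_runs(self, flat_landscape):
        specs = [EnsembleSpec("umbrella", z0=-1.0, k_bias=2.0, ensemble_id=0),
                 EnsembleSpec("umbrella", z0=1.0, k_bias=2.0, ensemble_id=1)]
        batch = simulate_batch(flat_landscape, specs, 1000, 1e-3, [7, 8])
        for spec, seed, t_b in zip(specs, [7, 8], batch):
            single = simulate_trajectory(flat_landscape, spec, 1000, 1e-3,
                                         seed=seed).trajectories[0]
            assert np.array_equal(single.z, t_b.z)


class TestEquilibriumLaws:
    def test_free_diffusion_msd(self):
        # on a flat potential the MSD over lag t is 2 D t (within 3 SE);
        # use a wide domain so walls are never touched
        ls = Landscape(terms=(), z_range=(-4000.0, 4000.0), D_z=50.0,
                       wall_k=0.0)
        traj = simulate_trajectory(ls, UNBIASED, 20_000, 1e-3,
                                   seed=1).trajectories[0]
        lag = 100
        disp = traj.z[lag:] - traj.z[:-lag]
        msd = np.mean(disp**2)
        expected = 2 * ls.D_z * lag * 1e-3
        se = np.std(disp**2) / np.sqrt(len(disp) / (2 * lag))
        assert abs(msd - expected) < 3 * se

    def test_umbrella_variance_is_kbt_over_k(self, flat_landscape):
        # Boltzmann variance of a harmonic restraint: var(z) = kBT / k
        spec = EnsembleSpec("umbrella", z0=0.0, k_bias=10.0, ensemble_id=0)
        traj = simulate_trajectory(flat_landscape, spec, 100_000, 1e-4,
                                   seed=3).trajectories[0]
        var = np.var(traj.z[2000:])
        expected = flat_landscape.kBT / 10.0
        assert var == pytest.approx(expected, rel=0.1)

    def test_unbiased_histogram_matches_boltzmann(self):
        # chi-square of the empirical z histogram against the analytic
        # stationary density at alpha = 0.01.  Frames along a diffusive
        # trajectory are correlated, so the histogram uses >= 1e5 frames
        # from 200 burned-in parallel chains while the test statistic is
        # scaled to a conservative effective sample count (one independent
        # sample per two relaxation times per chain).
        ls = build_landscape(
            wells=[{"depth": -1.0, "z0": 0.0, "sigma_z": 1.5}],
            z_range=(-5.0, 5.0), D_z=50.0)
        n_chains = 200
        specs = [EnsembleSpec("unbiased", ensemble_id=i)
                 for i in range(n_chains)]
        rng = np.random.default_rng(0)
        z0 = rng.uniform(-5, 5, n_chains)
        burn, run, dt = 10_000, 20_000, 2e-4
        trajs = simulate_batch(ls, specs, burn + run, dt,
                               seeds=list(range(n_chains)), z_init=z0,
                               equil_steps=burn, stride=10)
        z = np.concatenate([t.z for t in trajs])
        assert len(z) >= 1e5
        gt = ground_truth_profile(ls, bins=20)
        edges = np.linspace(*ls.z_range, 21)
        freq_obs, _ = np.histogram(z, bins=edges)
        freq_obs = freq_obs / freq_obs.sum()
        tau_steps = 1000  # slowest relaxation across the domain, in steps
        n_eff = n_chains * run // (2 * tau_steps)
        chi2 = n_eff * np.sum((freq_obs - gt.density) ** 2 / gt.density)
        assert chi2 < stats.chi2.ppf(0.99, len(edges) - 2)

    def test_window_mean_at_biased_minimum(self, twowell):
        # each window's mean z sits at the minimizer of G + bias (3 SE)
        specs = window_ladder(-5.0, 5.0, spacing=2.5, k_bias=10.0)
        trajs = simulate_batch(twowell, specs, 50_000, 1e-4,
                               seeds=list(range(len(specs))), equil_steps=5000)
        gt = ground_truth_profile(twowell, bins=2000)
        for spec, t in zip(specs, trajs):
            total = gt.profile + spec.bias_energy(gt.z_centers)
            z_min_region = gt.z_centers[np.argmin(total)]
            n_eff = len(t.z) / 20
            se = np.std(t.z) / np.sqrt(n_eff)
            assert abs(np.mean(t.z) - z_min_region) < 3 * se + 0.05


class TestLadderAndStability:
    def test_window_ladder_spacing_and_count(self):
        specs = window_ladder(-35.0, 40.0, spacing=0.5, k_bias=10.0)
        assert len(specs) == 151
        assert all(s.k_bias == 10.0 for s in specs)
        centers = np.array([s.z0 for s in specs])
        assert np.allclose(np.diff(centers), 0.5)

    def test_unstable_step_raises(self, twowell):
        spec = EnsembleSpec("umbrella", z0=0.0, k_bias=10.0, ensemble_id=0)
        with pytest.raises(ValueError, match="unstable"):
            simulate_trajectory(twowell, spec, 100, 0.01, seed=0)

    def test_negative_steps_raise(self, flat_landscape):
        with pytest.raises(ValueError):
            simulate_trajectory(flat_landscape, UNBIASED, -5, 1e-3, seed=0)

    def test_campaign_has_one_spec_per_trajectory(self, small_campaign):
        for t in small_campaign:
            assert t.ensemble_id in small_campaign.specs


class TestFeatures:
    def test_feature_zero_is_conformational_coordinate(self, twowell):
        trajs = simulate_trajectory(twowell, UNBIASED, 2000, 1e-4, seed=2)
        out = emit_features(trajs, D=4, snr=1e12, seed=0)
        t = out.trajectories[0]
        assert np.allclose(t.features[:, 0], t.c, atol=1e-9)

    def test_pure_noise_feature_uncorrelated(self):
        # a feature that is only noise has |r| with c below 0.1 at n = 1e4
        rng = np.random.default_rng(0)
        c = rng.standard_normal(10_000)
        noise = rng.standard_normal(10_000)
        r = np.corrcoef(c, noise)[0, 1]
        assert abs(r) < 0.1

    def test_default_dimension_is_105(self, twowell):
        trajs = simulate_trajectory(twowell, UNBIASED, 200, 1e-4, seed=2)
        out = emit_features(trajs, seed=0)
        assert out.trajectories[0].n_features == 105
        assert len(out.trajectories[0].sensor_z) == 105

    @pytest.mark.parametrize("kwargs", [dict(D=1), dict(snr=0.0)])
    def test_invalid_feature_args(self, twowell, kwargs):
        trajs = simulate_trajectory(twowell, UNBIASED, 50, 1e-4, seed=2)
        with pytest.raises(ValueError):
            emit_features(trajs, seed=0, **{"D": 8, "snr": 10.0, **kwargs})


class TestIO:
    def test_round_trip(self, tmp_path, small_campaign):
        sub = small_campaign.trajectories[:2]
        from memmpath.simulate import TrajectoryEnsemble
        ens = TrajectoryEnsemble(sub, dict(small_campaign.specs))
        write_trajectories(ens, str(tmp_path))
        back = read_trajectories(str(tmp_path))
        assert len(back) == 2
        for a, b in zip(ens, back):
            assert np.allclose(a.z, b.z, atol=1e-6)
            assert np.allclose(a.features, b.features, atol=1e-6)
            assert a.ensemble_id == b.ensemble_id
        sa = ens.specs[sub[0].ensemble_id]
        sb = back.specs[sub[0].ensemble_id]
        assert sa.kind == sb.kind and sa.k_bias == sb.k_bias
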