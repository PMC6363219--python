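"""tICA estimation, correlation-based selection, density-proximity selection."""

import numpy as np
import pytest

from memmpath.density import DensityGrid
from memmpath.simulate import EnsembleSpec, Trajectory, TrajectoryEnsemble
from memmpath.tica import (TicaModel, correlate_features_to_tics,
                           estimate_tica, select_features_near_density)


def _ensemble_from_features(X, dt=1.0):
    t = Trajectory(z=np.zeros(len(X)), c=np.zeros(len(X)), dt=dt,
                   ensemble_id=0, seed=0, features=np.asarray(X, float))
    return TrajectoryEnsemble([t], {0: EnsembleSpec("unbiased")})


class TestEstimation:
    def test_white_noise_has_no_slow_modes(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100_000, 5))
        model = estimate_tica(_ensemble_from_features(X), lag_ns=1.0,
                              n_components=4)
        assert np.all(np.abs(model.eigenvalues) < 0.05)

    def test_telegraph_process_eigenvalue(self):
        # two-state jump process with per-step flip probability q has
        # autocorrelation (1 - 2q)^L at lag L; the leading tICA eigenvalue
        # must match within 3 SE
        q, lag, n = 0.05, 5, 100_000
        rng = np.random.default_rng(2)
        flips = rng.random(n) < q
        state = 1.0 - 2.0 * (np.cumsum(flips) % 2)
        X = np.column_stack([state + 0.01 * rng.standard_normal(n),
                             -0.5 * state + 0.01 * rng.standard_normal(n)])
        model = estimate_tica(_ensemble_from_features(X), lag_ns=float(lag),
                              n_components=1)
        expected = (1 - 2 * q) ** lag
        lam_step = 1 - 2 * q
        tau_int = (1 + lam_step) / (1 - lam_step)
        se = np.sqrt((1 - expected**2) / (n / (2 * tau_int)))
        assert abs(model.eigenvalues[0] - expected) < 3 * se

    def test_eigenvalues_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        base = np.cumsum(rng.standard_normal((20_000, 3)), axis=0) * 0.01
        X = base + rng.standard_normal((20_000, 3))
        m1 = estimate_tica(_ensemble_from_features(X), lag_ns=2.0,
                           n_components=2)
        scale = np.array([2.0, 0.5, 7.0])
        shift = np.array([1.0, -3.0, 0.2])
        m2 = estimate_tica(_ensemble_from_features(X * scale + shift),
                           lag_ns=2.0, n_components=2)
        assert np.allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)

    def test_training_projection_has_unit_variance(self):
        rng = np.random.default_rng(4)
        X = np.cumsum(rng.standard_normal((30_000, 4)), axis=0) * 0.01 \
            + rng.standard_normal((30_000, 4))
        model = estimate_tica(_ensemble_from_features(X), lag_ns=1.0,
                              n_components=2)
        Y = model.transform(X)
        assert np.allclose(Y.var(axis=0), 1.0, atol=0.01)

    def test_single_slow_mode_recovered_as_tic0(self):
        # unbiased dynamics on a flat-z landscape whose conformational
        # coordinate relaxes ~40x slower than z: c is the single slow mode
        # and tIC0 must track it
        from memmpath.landscape import Landscape
        from memmpath.simulate import emit_features, simulate_trajectory
        ls = Landscape(terms=(), z_range=(-10.0, 10.0), D_z=50.0, D_c=0.02)
        trajs = simulate_trajectory(ls, EnsembleSpec("unbiased"), 100_000,
                                    2e-4, seed=9, stride=10)
        trajs = emit_features(trajs, D=8, snr=20.0, seed=1)
        model = estimate_tica(trajs, lag_ns=0.1, n_components=2)
        t = trajs.trajectories[0]
        tic0 = model.transform(t.features)[:, 0]
        assert abs(np.corrcoef(tic0, t.c)[0, 1]) > 0.9

    def test_short_trajectory_skipped(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError):
            estimate_tica(_ensemble_from_features(X), lag_ns=10.0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((5000, 3))
        model = estimate_tica(_ensemble_from_features(X), lag_ns=1.0)
        path = str(tmp_path / "tica.tsv")
        model.save(path)
        back = TicaModel.load(path)
        assert np.allclose(back.eigenvalues, model.eigenvalues)
        assert np.allclose(back.components, model.components)
        assert np.allclose(back.transform(X), model.transform(X))


class TestCorrelationSelection:
    def _fixture(self):
        rng = np.random.default_rng(6)
        slow = np.cumsum(rng.standard_normal(50_000)) * 0.02
        X = np.column_stack([
            slow + 0.05 * rng.standard_normal(50_000),  # tracks the slow mode
            rng.standard_normal(50_000),  # pure noise
            np.zeros(50_000),  # zero variance
        ])
        trajs = _ensemble_from_features(X)
        model = estimate_tica(trajs, lag_ns=1.0, n_components=1)
        return trajs, model

    def test_tracking_feature_selected_noise_not(self):
        trajs, model = self._fixture()
        sel = correlate_features_to_tics(trajs, model, threshold=0.6)
        assert 0 in sel.selected
        assert 1 not in sel.selected
        assert sel.abs_r[0, 0] > 0.99  # essentially identical to tIC0

    def test_zero_variance_feature_gets_zero(self):
        trajs, model = self._fixture()
        sel = correlate_features_to_tics(trajs, model)
        assert sel.abs_r[2, 0] == 0.0
        assert 2 not in sel.selected

    def test_entity_pair_counts(self):
        trajs, model = self._fixture()
        sel = correlate_features_to_tics(trajs, model)
        # feature -> (entity_a, entity_b), mirroring residue-pair distances
        pairs = [(10, 20), (10, 30), (20, 30)]
        counts = sel.entity_pair_counts(pairs)
        assert counts == {10: 1, 20: 1}

    def test_report_table(self, tmp_path):
        trajs, model = self._fixture()
        sel = correlate_features_to_tics(trajs, model)
        path = tmp_path / "selection.tsv"
        sel.to_table(str(path))
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 4  # header + 3 features
        assert lines[1].split("\t")[-1] == "1"


class TestDensityProximity:
    def _grid(self, hot_voxels, dims=(8, 8, 8), spacing=1.0):
        values = np.zeros(dims)
        for v in hot_voxels:
            values[v] = 100.0
        values[0, 0, 0] = max(values[0, 0, 0], 1.0)  # nonzero bulk somewhere
        bulk = 1.0
        return DensityGrid(origin=np.zeros(3), spacing=np.full(3, spacing),
                           values=values, bulk_density=bulk,
                           normalized=values / bulk)

    def test_no_hotspot_empty_selection(self):
        grid = self._grid([])
        sel = select_features_near_density(grid, np.zeros((3, 3)),
                                           cutoff=4.4, factor=7.0)
        assert len(sel) == 0

    def test_cutoff_distinguishes_sensors(self):
        # one hot voxel centred at (0.5, 0.5, 0.5); sensors at 4.0 and 5.0 A
        grid = self._grid([(0, 0, 0)])
        centre = np.full(3, 0.5)
        sensors = np.vstack([centre + [4.0, 0, 0], centre + [5.0, 0, 0]])
        sel = select_features_near_density(grid, sensors, cutoff=4.4,
                                           factor=7.0)
        assert sel.tolist() == [0]

    def test_invalid_cutoff(self):
        grid = self._grid([(1, 1, 1)])
        with pytest.raises(ValueError):
            select_features_near_density(grid, np.zeros((1, 3)), cutoff=0.0)
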