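"""Constant-pH mixing, bulk coupling and concentration-dependent kinetics."""

import numpy as np
import pytest

from memmpath.constants import KBT_310, mM_to_per_nm3
from memmpath.coarse import GROUP_Z_RANGES
from memmpath.discretize import MicrostateMap
from memmpath.kinetics import (CoarseKinetics, concentration_kinetics,
                               couple_to_bulk, ctmc_mfpt,
                               estimate_capture_probability,
                               mix_protonation_states, rate_matrix_from_T)
from memmpath.tram import MEMM


def metropolis_chain(G, kBT=KBT_310, hop=0.1):
    """Reversible nearest-neighbour chain with Boltzmann(G) stationary law."""
    n = len(G)
    T = np.zeros((n, n))
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                T[i, j] = hop * min(1.0, np.exp(-(G[j] - G[i]) / kBT))
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    return T


def make_memm(G, n_zbins=None, lag_ns=0.1, kBT=KBT_310):
    G = np.asarray(G, float)
    n = len(G)
    n_zbins = n_zbins or n
    smap = MicrostateMap(z_edges=np.arange(n_zbins + 1, dtype=float),
                         cluster_centers=np.zeros((n // n_zbins, 1)))
    pi = np.exp(-G / kBT)
    pi /= pi.sum()
    return MEMM(lag_frames=1, lag_ns=lag_ns, active_set=np.arange(n),
                pi=pi, G=G - G.min(), T=metropolis_chain(G, kBT),
                biased_f=np.zeros((1, n)), ensemble_shifts=np.zeros(1),
                map=smap, kBT=kBT, unbiased_index=0, converged=True,
                n_iter=1, log_likelihood_trace=np.zeros(1))


class TestRateConversion:
    def test_rate_matrix_rows_sum_to_zero(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        K = rate_matrix_from_T(T, lag_ns=0.5)
        assert np.allclose(K.sum(axis=1), 0.0, atol=1e-14)
        assert K[0, 1] == pytest.approx(0.2)

    def test_bad_lag(self):
        with pytest.raises(ValueError):
            rate_matrix_from_T(np.eye(2), 0.0)


class TestProtonationMix:
    BULK = (4, 5)

    def _pair(self, G_a, G_b, **kw):
        return mix_protonation_states(make_memm(G_a), make_memm(G_b),
                                      bulk_labels=self.BULK, **kw)

    def test_delta_g0_from_pka_and_ph(self):
        mix = self._pair(np.zeros(5), np.zeros(5), pKa=9.0, pH=7.0)
        expected = KBT_310 * np.log(10) * 2.0
        assert mix.delta_G0 == pytest.approx(expected, abs=1e-12)
        assert mix.delta_G0 == pytest.approx(2.837, abs=1e-3)

    def test_detailed_balance_against_boltzmann(self):
        G_a = np.array([0.0, -2.0, 1.0, 0.3, 0.0])
        G_b = np.array([0.5, 1.0, -0.5, 0.2, 0.1])
        mix = self._pair(G_a, G_b, pKa=9.0, pH=7.0)
        flux = mix.pi[:, None] * mix.K
        scale = np.abs(flux).max()
        assert np.max(np.abs(flux - flux.T)) < 1e-8 * max(scale, 1.0)
        assert np.allclose(mix.K.sum(axis=1), 0.0, atol=1e-12)

    def test_equal_energies_give_half_half(self):
        G = np.array([0.0, -1.0, 0.5, 0.2, 0.0])
        mix = self._pair(G, G, pKa=7.0, pH=7.0)  # dG0 = 0
        assert np.allclose(mix.p_alpha_z, 0.5, atol=1e-12)
        # combined free energy gains -kBT ln 2 uniformly: relative profile
        # equals the single-variant profile
        g_single = G - G.min()
        assert np.allclose(mix.G_combined_z, g_single, atol=1e-10)

    def test_large_shift_recovers_neutral_model(self):
        G_a = np.array([0.0, -2.0, 1.0, 0.3, 0.0])
        G_b = np.array([0.5, 1.0, -0.5, 0.2, 0.1])
        mix = self._pair(G_a, G_b, pKa=40.0, pH=7.0)  # dG0 -> +inf
        assert np.all(mix.p_alpha_z < 1e-10)
        assert np.allclose(mix.G_combined_z, G_b - G_b.min(), atol=1e-8)

    def test_marginal_protonation_probability_is_exact(self):
        G_a = np.array([0.0, -2.0, 1.0, 0.3, 0.0])
        G_b = np.array([0.5, 1.0, -0.5, 0.2, 0.1])
        mix = self._pair(G_a, G_b, pKa=9.0, pH=7.0)
        # stationary marginal of the product chain per z bin
        zl = mix.z_labels()
        na = mix.n_alpha
        for zb in range(1, 6):
            sel = zl == zb
            tot = mix.pi[sel].sum()
            alpha = mix.pi[:na][zl[:na] == zb].sum()
            assert alpha / tot == pytest.approx(mix.p_alpha_z[zb - 1],
                                                abs=1e-12)

    def test_mismatched_maps_rejected(self):
        a = make_memm(np.zeros(5))
        b = make_memm(np.zeros(4))
        with pytest.raises(ValueError, match="map"):
            mix_protonation_states(a, b, bulk_labels=self.BULK)

    def test_nonpositive_koff_rejected(self):
        a = make_memm(np.zeros(5))
        with pytest.raises(ValueError):
            mix_protonation_states(a, a, k_off=0.0, bulk_labels=self.BULK)


class TestCaptureProbability:
    def test_counted_episodes(self):
        # enter(4) -> capture(0); re-arm at 6; enter(4) -> escape(6)
        z = [np.array([6.0, 4.0, 0.0, 4.0, 6.0, 4.0, 6.0])]
        gamma = estimate_capture_probability(z, z_mouth=5.0, z_bind=1.0)
        assert gamma == pytest.approx(0.5)

    def test_every_entry_binds(self):
        z = [np.array([6.0, 0.0, 6.0, 0.0, 6.0])]
        assert estimate_capture_probability(z, 5.0, 1.0) == 1.0

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            estimate_capture_probability([np.array([9.0, 9.0])], 5.0, 1.0)


def two_state_model(k_in=1e4, k_off=1.0):
    """extracellular encounter state + bound state."""
    K = np.array([[-k_in, k_in], [k_off, -k_off]])
    pi = np.array([k_off, k_in])
    pi = pi / pi.sum()
    return CoarseKinetics(K=K, pi=pi, labels=["extracellular", "bound"])


class TestBulkCoupling:
    def test_smoluchowski_rate_arithmetic(self):
        # 4 pi * 20 nm^2/us * 1.5 nm * 0.0903 nm^-3 = 34.05 /us
        model = two_state_model()
        bulk = couple_to_bulk(model, conc_EC_mM=150.0, D_nm2_us=20.0,
                              r_EC_nm=1.5, gamma=0.5)
        assert mM_to_per_nm3(150.0) == pytest.approx(0.0903, abs=2e-4)
        assert bulk.k_on_ns * 1e3 == pytest.approx(34.05, abs=0.05)

    def test_zero_concentration_gives_infinite_binding(self):
        model = two_state_model()
        bulk = couple_to_bulk(model, conc_EC_mM=0.0, gamma=0.5)
        ecb = bulk.index_of("EC_bulk")
        bound = bulk.states_in_group("bound")
        assert bulk.k_on_ns == 0.0
        assert ctmc_mfpt(bulk.Q, [ecb], bound) == np.inf

    def test_two_state_toy_affinity_closed_form(self):
        # effective on-rate k+ c gamma vs effective off-rate k_off (1-gamma):
        # Kd = k_off (1-gamma) / (k+ gamma)
        gamma, k_off = 0.5, 0.01
        model = two_state_model(k_in=1e5, k_off=k_off)
        grid = np.array([0.5, 1.0, 5.0, 20.0, 100.0, 500.0])
        scan = concentration_kinetics(model, grid, D_nm2_us=20.0,
                                      r_EC_nm=1.5, gamma=gamma)
        k_plus_per_mM = 4 * np.pi * 20.0 * 1.5 * mM_to_per_nm3(1.0) * 1e-3
        kd_expected = k_off * (1 - gamma) / (gamma * k_plus_per_mM)
        assert scan.affinity_mM == pytest.approx(kd_expected, rel=1e-3)
        # isotherm shape: occupancy = c/(c + Kd)
        occ_expected = grid / (grid + kd_expected)
        assert np.allclose(scan.occupancy, occ_expected, atol=2e-3)

    def test_binding_time_halves_at_double_concentration(self):
        model = two_state_model(k_in=1e5)
        scan = concentration_kinetics(model, np.array([50.0, 100.0]),
                                      gamma=1.0)
        assert scan.binding_ns[0] / scan.binding_ns[1] \
            == pytest.approx(2.0, rel=0.01)

    def test_dissociation_and_egress_concentration_independent(self):
        K = np.array([
            [-0.011, 0.01, 0.001],
            [0.02, -0.04, 0.02],
            [0.001, 0.01, -0.011],
        ])
        pi = np.array([0.4, 0.2, 0.4])
        model = CoarseKinetics(K=K, pi=pi,
                               labels=["cytoplasmic", "bound",
                                       "extracellular"])
        grid = np.array([10.0, 100.0, 1000.0])
        scan = concentration_kinetics(model, grid, gamma=(0.999, 0.5))
        assert np.ptp(scan.dissociation_ns) / scan.dissociation_ns[0] < 0.01
        assert np.ptp(scan.egress_ns) / scan.egress_ns[0] < 0.01

    def test_invalid_gamma(self):
        model = two_state_model()
        with pytest.raises(ValueError):
            couple_to_bulk(model, gamma=0.0)

    def test_no_extracellular_states_rejected(self):
        model = CoarseKinetics(K=np.array([[-1.0, 1.0], [1.0, -1.0]]),
                               pi=np.array([0.5, 0.5]),
                               labels=["bound", "unassigned"])
        with pytest.raises(ValueError, match="extracellular"):
            couple_to_bulk(model)

    def test_printed_gamma_form_exposed(self):
        model = two_state_model(k_in=1.0)
        flux = couple_to_bulk(model, gamma=0.2, gamma_form="flux")
        printed = couple_to_bulk(model, gamma=0.2, gamma_form="printed")
        s = flux.labels.index("extracellular")
        # flux form: k_esc = k_in (1-g)/g = 4; printed: k_esc = k_in g/(1-g)
        assert flux.Q[s, 0] == pytest.approx(4.0)
        assert printed.Q[s, 0] == pytest.approx(0.25)


class TestCtmcMfpt:
    def test_simple_two_state_rate(self):
        Q = np.array([[-2.0, 2.0], [1.0, -1.0]])
        assert ctmc_mfpt(Q, [0], [1]) == pytest.approx(0.5)

    def test_linear_solve_matches_simulation(self):
        rng = np.random.default_rng(1)
        Q = np.array([
            [-3.0, 2.0, 1.0, 0.0, 0.0],
            [1.0, -2.0, 0.5, 0.5, 0.0],
            [0.5, 0.5, -2.0, 0.5, 0.5],
            [0.0, 1.0, 1.0, -2.5, 0.5],
            [0.1, 0.0, 0.4, 0.5, -1.0],
        ])
        predicted = ctmc_mfpt(Q, [0], [4])
        times = []
        for _ in range(3000):
            s, t = 0, 0.0
            while s != 4:
                rates = Q[s].copy()
                rates[s] = 0.0
                total = rates.sum()
                t += rng.exponential(1.0 / total)
                s = rng.choice(5, p=rates / total)
            times.append(t)
        times = np.asarray(times)
        se = times.std() / np.sqrt(len(times))
        assert abs(predicted - times.mean()) < 3 * se
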