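"""Discrete TRAM: multi-ensemble Markov-model estimation.

TRAM (transition-based reweighting analysis method) jointly analyses
discrete trajectories collected under several thermodynamic ensembles
(umbrella windows plus unbiased runs).  It couples, per ensemble k and
microstate i, a reversible transition-matrix likelihood with a
local-equilibrium reweighting of the samples, through the self-consistent
equations (all free energies dimensionless, in kBT):

    v_i^k  <-  sum_j (c_ij^k + c_ji^k) v_i^k e^{-f_j^k}
               / (v_i^k e^{-f_j^k} + v_j^k e^{-f_i^k})

    R_i^k   =  sum_j (c_ij^k + c_ji^k) v_j^k e^{-f_i^k}
               / (v_i^k e^{-f_j^k} + v_j^k e^{-f_i^k})
               + N_i^k - sum_j c_ji^k

    f_i^k  <- -ln sum_{x in X_i} e^{-b^k(x)} / sum_l R_i^l e^{f_i^l - b^l(x)}

where c_ij^k are transition counts at the lag in ensemble k, N_i^k the
number of samples of ensemble k in state i, b^k(x) the bias energy of
sample x under ensemble k, and X_i all samples (any ensemble) in state i.
At the fixed point, exp(-f_i^k0) of the unbiased ensemble k0 is the
unbiased stationary weight of microstate i, and the unbiased reversible
transition matrix is

    T_ij = (c_ij^k0 + c_ji^k0) e^{-f_j^k0}
           / (v_i^k0 e^{-f_j^k0} + v_j^k0 e^{-f_i^k0}),   i != j

with the diagonal completing each row to 1.  With a single unbiased
ensemble the equations reduce to the reversible MSM maximum-likelihood
estimator.  Everything runs in log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
from scipy.special import logsumexp

from .constants import KBT_310
from .discretize import DiscreteTrajectories, MicrostateMap
from .msm import count_matrix, largest_connected_set, reversible_mle
from .simulate import TrajectoryEnsemble

__all__ = [
    "MEMM",
    "FreeEnergyProfile",
    "estimate_tram",
    "implied_timescales",
    "implied_timescales_ladder",
    "free_energy_profile",
    "bootstrap_resample",
    "median_quartiles",
]

logger = logging.getLogger(__name__)

_NEG_INF = -np.inf


@dataclass
class MEMM:
    """Multi-ensemble Markov model on the active microstate set."""

    lag_frames: int
    lag_ns: float
    active_set: np.ndarray  # microstate ids (into map), sorted
    pi: np.ndarray  # stationary probabilities on the active set
    G: np.ndarray  # microstate free energies, kcal/mol, min anchored at 0
    T: np.ndarray  # unbiased reversible transition matrix at the lag
    biased_f: np.ndarray  # (K, n_active) dimensionless state free energies
    ensemble_shifts: np.ndarray  # (K,) per-ensemble free energies, kBT units
    map: MicrostateMap
    kBT: float
    unbiased_index: int
    converged: bool
    n_iter: int
    log_likelihood_trace: np.ndarray
    warning: str | None = None
    kinetic_set: np.ndarray | None = None  # indices into the active set

    @property
    def n_states(self) -> int:
        return len(self.active_set)

    def kinetic_model(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(T, pi, microstate ids) restricted to the unbiased-connected set.

        States the unbiased ensemble never linked by a transition are
        excluded (they would be absorbing self-loops); outgoing deficit is
        folded into the diagonal, which preserves detailed balance.
        """
        sub = (np.arange(self.n_states) if self.kinetic_set is None
               else self.kinetic_set)
        T = self.T[np.ix_(sub, sub)].copy()
        np.fill_diagonal(T, np.diag(T) + (1.0 - T.sum(axis=1)))
        pi = self.pi[sub]
        pi = pi / pi.sum()
        return T, pi, self.active_set[sub]

    def full_pi(self) -> np.ndarray:
        """pi over all microstates; unvisited states get 0."""
        out = np.zeros(self.map.n_microstates)
        out[self.active_set] = self.pi
        return out

    def full_G(self) -> np.ndarray:
        """G over all microstates; unvisited states get +inf."""
        out = np.full(self.map.n_microstates, np.inf)
        out[self.active_set] = self.G
        return out


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile G(z) with optional bootstrap quartile errors."""

    z_centers: np.ndarray
    G: np.ndarray  # kcal/mol, min anchored at 0, +inf on empty bins
    err_lo: np.ndarray | None = None  # median - 1st quartile
    err_hi: np.ndarray | None = None  # 3rd quartile - median

    def to_table(self, path: str) -> None:
        cols = [self.z_centers, self.G]
        header = "z_center\tG_kcal_mol"
        if self.err_lo is not None:
            cols += [self.err_lo, self.err_hi]
            header += "\terr_lo\terr_hi"
        np.savetxt(path, np.column_stack(cols), delimiter="\t",
                   header=header, comments="")


#: placeholder free energy for (ensemble, state) pairs whose bias exceeds the
#: cutoff everywhere; their Boltzmann weight is numerically zero.
_F_FAR = 1e6


@numba.njit(cache=True)
def _ladd(a, b):
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a > b:
        return a + np.log1p(np.exp(b - a))
    return b + np.log1p(np.exp(a - b))


@numba.njit(cache=True)
def _tram_iterate(pk, pi_, pj, plogS, dk, di, dj, dcount, dlogS,
                  K, m, f, log_v, log_extra,
                  nbr_ptr, nbr_k, nbr_b, state_sorted, ens_sorted, bown,
                  max_iter, tol, ll_every, ll_arr, f_big):
    """Self-consistent TRAM iteration over the sparse pair/sample structure.

    All logsumexp reductions are streamed with running-maximum rescaling.
    Returns the converged (f, log_v) plus iteration diagnostics; the
    log-likelihood is recorded every ``ll_every`` iterations into ll_arr.
    """
    n = len(state_sorted)
    nP = len(pk)
    log_v_new = np.empty((K, m))
    log_R = np.empty((K, m))
    LRf = np.empty((K, m))
    log_d = np.empty(n)
    mx = np.empty((K, m))
    acc = np.empty((K, m))
    f_new = np.empty((K, m))
    n_ll = 0
    it = 0
    delta = np.inf
    converged = False
    while it < max_iter:
        it += 1
        # --- Lagrange multiplier update ---
        mx[:] = _NEG_INF
        acc[:] = 0.0
        for p in range(nP):
            k, i, j = pk[p], pi_[p], pj[p]
            pij = log_v[k, i] - f[k, j]
            pji = log_v[k, j] - f[k, i]
            val = plogS[p] + pij - _ladd(pij, pji)
            if val > mx[k, i]:
                if mx[k, i] == _NEG_INF:
                    acc[k, i] = 1.0
                else:
                    acc[k, i] = acc[k, i] * np.exp(mx[k, i] - val) + 1.0
                mx[k, i] = val
            else:
                acc[k, i] += np.exp(val - mx[k, i])
        for k in range(K):
            for i in range(m):
                log_v_new[k, i] = (mx[k, i] + np.log(acc[k, i])
                                   if mx[k, i] > _NEG_INF else _NEG_INF)
        # --- R factors (with updated multipliers) ---
        mx[:] = _NEG_INF
        acc[:] = 0.0
        for p in range(nP):
            k, i, j = pk[p], pi_[p], pj[p]
            pij = log_v_new[k, i] - f[k, j]
            pji = log_v_new[k, j] - f[k, i]
            val = plogS[p] + pji - _ladd(pij, pji)
            if val > mx[k, i]:
                if mx[k, i] == _NEG_INF:
                    acc[k, i] = 1.0
                else:
                    acc[k, i] = acc[k, i] * np.exp(mx[k, i] - val) + 1.0
                mx[k, i] = val
            else:
                acc[k, i] += np.exp(val - mx[k, i])
        for k in range(K):
            for i in range(m):
                r = (mx[k, i] + np.log(acc[k, i])
                     if mx[k, i] > _NEG_INF else _NEG_INF)
                lr = _ladd(r, log_extra[k, i])
                log_R[k, i] = lr
                LRf[k, i] = lr + f[k, i] if lr > _NEG_INF else _NEG_INF
        # --- sample weights ---
        for x in range(n):
            s = state_sorted[x]
            m_x = _NEG_INF
            a_x = 0.0
            for t in range(nbr_ptr[x], nbr_ptr[x + 1]):
                val = LRf[nbr_k[t], s] - nbr_b[t]
                if val == _NEG_INF:
                    continue
                if val > m_x:
                    if m_x == _NEG_INF:
                        a_x = 1.0
                    else:
                        a_x = a_x * np.exp(m_x - val) + 1.0
                    m_x = val
                else:
                    a_x += np.exp(val - m_x)
            log_d[x] = m_x + np.log(a_x) if m_x > _NEG_INF else _NEG_INF
        # --- free-energy update ---
        mx[:] = _NEG_INF
        acc[:] = 0.0
        for x in range(n):
            s = state_sorted[x]
            for t in range(nbr_ptr[x], nbr_ptr[x + 1]):
                k = nbr_k[t]
                val = -nbr_b[t] - log_d[x]
                if val > mx[k, s]:
                    if mx[k, s] == _NEG_INF:
                        acc[k, s] = 1.0
                    else:
                        acc[k, s] = acc[k, s] * np.exp(mx[k, s] - val) + 1.0
                    mx[k, s] = val
                else:
                    acc[k, s] += np.exp(val - mx[k, s])
        delta = 0.0
        for k in range(K):
            for i in range(m):
                v = (-(mx[k, i] + np.log(acc[k, i]))
                     if mx[k, i] > _NEG_INF else f_big)
                f_new[k, i] = v
                if v < f_big and f[k, i] < f_big:
                    d = abs(v - f[k, i])
                    if d > delta:
                        delta = d
                f[k, i] = v
        for k in range(K):
            for i in range(m):
                log_v[k, i] = log_v_new[k, i]
        done = delta < tol
        if it % ll_every == 0 or done:
            ll = 0.0
            for p in range(len(dk)):
                k, i, j = dk[p], di[p], dj[p]
                pij = log_v[k, i] - f[k, j]
                pji = log_v[k, j] - f[k, i]
                ll += dcount[p] * (dlogS[p] - f[k, j] - _ladd(pij, pji))
            for x in range(n):
                ll += f[ens_sorted[x], state_sorted[x]] - bown[x] - log_d[x]
            ll_arr[n_ll] = ll
            n_ll += 1
        if done:
            converged = True
            break
    return f, log_v, it, delta, n_ll, converged


def estimate_tram(
    data: DiscreteTrajectories,
    lag: int = 200,
    tol: float = 1e-10,
    max_iter: int = 50_000,
    dt_ns: float | None = None,
    kBT: float = KBT_310,
    unbiased_ensemble: int | None = None,
    ll_every: int = 10,
    bias_cutoff: float = 50.0,
) -> MEMM:
    """Self-consistent discrete TRAM estimate.

    Parameters
    ----------
    data
        Discrete trajectories with the full (ensemble x frame) bias matrix.
    lag
        Lag time in frames (sliding-window transition counting).
    tol
        Convergence threshold on the maximum change of any biased state free
        energy per iteration (dimensionless).
    unbiased_ensemble
        Row of the bias matrix corresponding to the unbiased ensemble;
        defaults to the row whose bias is identically zero.
    """
    K = data.n_ensembles
    M = data.map.n_microstates
    bias = data.bias
    if unbiased_ensemble is None:
        zero_rows = np.flatnonzero(np.all(bias == 0.0, axis=1))
        if len(zero_rows) == 0:
            raise ValueError("no unbiased ensemble found (no all-zero bias row)")
        unbiased_ensemble = int(zero_rows[-1])

    # per-ensemble transition counts at the lag
    C = np.zeros((K, M, M))
    for d, k in zip(data.dtrajs, data.ensemble_ids):
        if len(d) > lag:
            np.add.at(C[k], (d[:-lag], d[lag:]), 1.0)

    # active set: largest component of transitions pooled over ensembles
    total = C.sum(axis=0)
    lcc = largest_connected_set(total)
    occupied = np.flatnonzero(data.microstate_counts() > 0)
    active = np.intersect1d(lcc, occupied)
    if len(active) < M:
        n_frag = M - len(active)
        logger.info("TRAM active set: %d of %d microstates (%d disconnected "
                    "or empty)", len(active), M, n_frag)
    if len(active) < 2:
        raise ValueError("disconnected count matrix: no usable active set; "
                         f"fragments outside states {active.tolist()}")
    back = -np.ones(M, dtype=int)
    back[active] = np.arange(len(active))
    m = len(active)
    Ca = C[:, active][:, :, active]
    S = Ca + np.transpose(Ca, (0, 2, 1))
    logS = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), _NEG_INF)
    c_in = Ca.sum(axis=1)  # counts into each state, per ensemble

    # flatten samples, restricted to the active set
    state_ix_full = np.concatenate(data.dtrajs)
    ens_ix_full = np.concatenate([
        np.full(len(d), k) for d, k in zip(data.dtrajs, data.ensemble_ids)])
    keep = back[state_ix_full] >= 0
    state_ix = back[state_ix_full[keep]]
    ens_ix = ens_ix_full[keep]
    B = bias[:, keep]  # (K, n)
    n = B.shape[1]
    Ncount = np.zeros((K, m))
    np.add.at(Ncount, (ens_ix, state_ix), 1.0)

    order = np.argsort(state_ix, kind="stable")
    state_sorted = state_ix[order]
    present = np.unique(state_sorted)
    if len(present) < m:
        raise ValueError("active states without samples; inconsistent input")
    B_ord = B[:, order]

    # init: WHAM on the microstate histograms (bias averaged per state)
    # brings f close to the fixed point; v start from outgoing counts
    f = _wham_init(B, state_ix, ens_ix, Ncount, m)
    with np.errstate(divide="ignore"):
        log_v = np.log(np.maximum(Ca.sum(axis=2), 1.0))
        log_extra = np.where(Ncount > c_in,
                             np.log(np.maximum(Ncount - c_in, 1e-300)), _NEG_INF)

    # sparse transition-pair structure (symmetrized counts)
    pk, pi_, pj = np.nonzero(S)
    plogS = logS[pk, pi_, pj]
    dk, di, dj = np.nonzero(Ca)
    dcount = Ca[dk, di, dj]
    dlogS = logS[dk, di, dj]

    # neighbor ensembles of each (sorted) sample: ensembles whose bias on
    # the frame is below the cutoff; others contribute exp(-b) < 1e-21 and
    # are dropped.  Unbiased ensembles (zero bias) are neighbors of all.
    near = B_ord < bias_cutoff
    nbr_ptr = np.zeros(n + 1, dtype=np.int64)
    nbr_ptr[1:] = np.cumsum(near.sum(axis=0))
    nbr_k = np.nonzero(near.T)[1].astype(np.int64)
    nbr_b = B_ord.T[near.T]
    ens_sorted = ens_ix[order].astype(np.int64)
    bown_sorted = B_ord[ens_sorted, np.arange(n)]
    f_big = _F_FAR

    ll_arr = np.empty(max_iter + 2)
    f, log_v, it, delta, n_ll, converged = _tram_iterate(
        pk.astype(np.int64), pi_.astype(np.int64), pj.astype(np.int64), plogS,
        dk.astype(np.int64), di.astype(np.int64), dj.astype(np.int64),
        dcount, dlogS,
        K, m, f, log_v, log_extra,
        nbr_ptr, nbr_k, nbr_b, state_sorted.astype(np.int64),
        ens_sorted, bown_sorted,
        max_iter, tol, ll_every, ll_arr, f_big,
    )
    ll_trace = list(ll_arr[:n_ll])
    logger.info("TRAM finished after %d iterations (max|df| = %.3e)", it, delta)

    warning = None
    if not converged:
        warning = f"TRAM did not converge in {max_iter} iterations (delta={delta:.2e})"
        warnings.warn(warning)

    k0 = unbiased_ensemble
    log_pi = -f[k0]
    log_pi -= logsumexp(log_pi)
    pi = np.exp(log_pi)

    # unbiased reversible transition matrix, symmetric-flux off-diagonals
    P0 = log_v[k0][:, None] - f[k0][None, :]
    denom0 = np.logaddexp(P0, P0.T)
    with np.errstate(invalid="ignore"):
        logT = logS[k0] - f[k0][None, :] - denom0
    T = np.where(np.isfinite(logT), np.exp(logT), 0.0)
    np.fill_diagonal(T, 0.0)
    rows = T.sum(axis=1)
    if np.any(rows > 1.0 + 1e-6):
        warnings.warn(
            f"off-diagonal row sums exceeded 1 by {rows.max() - 1.0:.2e} "
            "before diagonal completion; estimate may not be fully converged")
    if np.any(rows > 1.0):
        T /= np.maximum(rows, 1.0)[:, None]
        rows = T.sum(axis=1)
    np.fill_diagonal(T, 1.0 - rows)

    G = kBT * f[k0]
    G = G - G.min()
    shifts = -logsumexp(-f, axis=1)
    shifts = shifts - shifts[0]
    kin = largest_connected_set(S[k0] - np.diag(np.diag(S[k0])))
    if len(kin) < m:
        logger.info("kinetic (unbiased-connected) set: %d of %d active states",
                    len(kin), m)
    return MEMM(
        lag_frames=lag,
        lag_ns=lag * dt_ns if dt_ns is not None else float("nan"),
        active_set=active, pi=pi, G=G, T=T, biased_f=f,
        ensemble_shifts=shifts, map=data.map, kBT=kBT,
        unbiased_index=k0, converged=converged, n_iter=it,
        log_likelihood_trace=np.asarray(ll_trace), warning=warning,
        kinetic_set=kin,
    )


def _wham_init(B, state_ix, ens_ix, Ncount, m, n_iter=2000):
    """WHAM estimate of the biased state free energies, used to start TRAM.

    Uses the mean bias of the samples within each state as the per-(k, i)
    bias; the self-consistent histogram iteration then yields
    f_init[k, i] = g_k + b_ki - ln p_i up to a constant.
    """
    K = B.shape[0]
    bias_ki = np.zeros((K, m))
    cnt = np.zeros(m)
    np.add.at(cnt, state_ix, 1.0)
    for k in range(K):
        acc = np.zeros(m)
        np.add.at(acc, state_ix, B[k])
        bias_ki[k] = acc / np.maximum(cnt, 1.0)
    M_i = cnt
    N_k = Ncount.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_Mi = np.where(M_i > 0, np.log(np.maximum(M_i, 1e-300)), _NEG_INF)
        log_Nk = np.where(N_k > 0, np.log(np.maximum(N_k, 1e-300)), _NEG_INF)
    g = np.zeros(K)
    for _ in range(n_iter):
        log_p = log_Mi - logsumexp(
            log_Nk[:, None] + g[:, None] - bias_ki, axis=0)
        g_new = -logsumexp(log_p[None, :] - bias_ki, axis=1)
        if np.max(np.abs(g_new - g)) < 1e-10:
            g = g_new
            break
        g = g_new
    log_p = log_Mi - logsumexp(log_Nk[:, None] + g[:, None] - bias_ki, axis=0)
    log_p -= logsumexp(log_p)
    f = g[:, None] + bias_ki - log_p[None, :]
    return f


def implied_timescales(T: np.ndarray, lag_ns: float, n: int = 10,
                       imag_tol: float = 1e-8) -> np.ndarray:
    """Relaxation timescales -tau/ln(lambda_i) for the n slowest modes.

    Eigenvalues at (or beyond) 1 give infinite timescales.  Complex
    eigenvalues beyond ``imag_tol`` indicate a non-reversible input and
    raise.
    """
    evals = np.linalg.eigvals(T)
    if np.max(np.abs(evals.imag)) > imag_tol:
        raise ValueError("complex eigenvalues: transition matrix is not "
                         "reversible")
    ev = np.sort(evals.real)[::-1]
    ev = ev[1:n + 1]  # drop the stationary eigenvalue
    out = np.full(len(ev), np.inf)
    pos = (ev > 0) & (ev < 1)
    out[pos] = -lag_ns / np.log(ev[pos])
    out[ev <= 0] = np.nan  # faster than the lag; unresolved
    return out


def implied_timescales_ladder(
    dtrajs: list[np.ndarray],
    n_states: int,
    lags: list[int],
    dt_ns: float,
    n: int = 10,
) -> dict[int, np.ndarray]:
    """Implied timescales of the (unbiased) reversible MSM across a lag ladder.

    Convergence of these curves guides the TRAM lag choice.
    """
    out = {}
    for lag in lags:
        C = count_matrix(dtrajs, lag, n_states)
        lcc = largest_connected_set(C)
        T, _ = reversible_mle(C[np.ix_(lcc, lcc)], tol=1e-12)
        out[lag] = implied_timescales(T, lag * dt_ns, n=n)
    return out


def free_energy_profile(memm: MEMM) -> FreeEnergyProfile:
    """Integrate the conformational clusters out of the microstate energies.

    G(z) = -kBT ln sum_i exp(-Gbar(z, i)/kBT), min anchored at 0; z bins
    with no populated cluster report +inf.
    """
    smap = memm.map
    G_full = memm.full_G()
    gz = np.full(smap.n_zbins, np.inf)
    arr = G_full.reshape(smap.n_zbins, smap.n_clusters)
    finite = np.isfinite(arr)
    any_row = finite.any(axis=1)
    if not any_row.any():
        raise ValueError("all-empty profile")
    for zb in np.flatnonzero(any_row):
        vals = arr[zb][finite[zb]]
        gz[zb] = -memm.kBT * logsumexp(-vals / memm.kBT)
    gz = gz - gz[any_row].min()
    centers = 0.5 * (smap.z_edges[:-1] + smap.z_edges[1:])
    return FreeEnergyProfile(z_centers=centers, G=gz)


def bootstrap_resample(
    trajs: TrajectoryEnsemble,
    n_samples: int = 12,
    frac: float = 0.9,
    seed: int = 0,
) -> list[TrajectoryEnsemble]:
    """Whole-trajectory bootstrap of the unbiased data.

    Each sample draws unbiased trajectories with replacement until their
    cumulative frame count reaches ``frac`` of the full unbiased total, and
    keeps the complete umbrella set unchanged.  Downstream summaries use the
    median over {samples + full estimate} with 1st/3rd-quartile errors.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    unbiased = [t for t in trajs if trajs.specs[t.ensemble_id].kind == "unbiased"]
    biased = [t for t in trajs if trajs.specs[t.ensemble_id].kind != "unbiased"]
    if not unbiased:
        raise ValueError("no unbiased trajectories to resample")
    total = sum(len(t) for t in unbiased)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        chosen = []
        got = 0
        while got < frac * total:
            t = unbiased[rng.integers(len(unbiased))]
            chosen.append(t)
            got += len(t)
        out.append(TrajectoryEnsemble(biased + chosen, dict(trajs.specs),
                                      trajs.landscape))
    return out


def median_quartiles(values) -> tuple[float, float, float]:
    """(median, 1st quartile, 3rd quartile) of a set of estimates."""
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)
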