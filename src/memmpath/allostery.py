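"""Two-state receptor model of sodium modulation of ligand binding.

The receptor equilibrates between inactive and active conformations with
equilibrium constants tau_u (ligand-free) and tau_b (ligand-bound), and the
ligand binds the two conformations with affinities K and K*.  The fraction
of ligand-bound receptors is f_b = [L]/(L50 + [L]) with

    L50 = K* (1 + tau_u) / (1 + tau_b),

so for antagonists (tau_u ~ tau_b) L50 is unaffected by the conformational
equilibrium, while for full agonists (tau_b << tau_u) L50 ~ K* (1 + tau_u).
Sodium shifts tau_u through the ratio of conformational partition
functions; with rho([Na+]) = L50([Na+])/L50(0), the percent change of bound
ligand at ligand concentration x = [L]/L50(0) is

    df_b/f_b = (1 - rho) / (x + rho).

The partition functions are evaluated from the estimated state free
energies with grand-canonical weighting of the ion-bound states: each
bound-state Boltzmann weight scales linearly with bulk concentration
relative to the reference concentration at which the models were sampled.
rho is a ratio of ratios (activation free energy mu cancels), so only the
relative bound/unbound weights of each conformation enter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StateWeights",
    "TwoStateReceptor",
    "partition_function",
    "partition_ratio",
    "rho_of_sodium",
    "ligand_l50",
    "bound_fraction",
    "percent_change_curve",
    "sodium_ic50",
    "NotReached",
]

logger = logging.getLogger(__name__)


class NotReached(Exception):
    """The requested reduction level is never reached on the curve."""


@dataclass
class StateWeights:
    """Dimensionless state energies with an ion-bound mask, for one model."""

    energies_kBT: np.ndarray
    bound: np.ndarray  # boolean mask over states

    def __post_init__(self) -> None:
        self.energies_kBT = np.asarray(self.energies_kBT, float)
        self.bound = np.asarray(self.bound, bool)
        if self.energies_kBT.shape != self.bound.shape:
            raise ValueError("energies and bound mask must align")

    @classmethod
    def from_memm(cls, memm, macro=None) -> "StateWeights":
        """Build from a fitted MEMM.

        With a coarse :class:`~memmpath.coarse.MacrostateModel`, energies
        come from the kinetic submodel and bound states are the bound-group
        macrostates; otherwise all active microstates are used with the
        bound z-label range.
        """
        from .coarse import group_label_ranges
        if macro is not None:
            _, pi, _ = memm.kinetic_model()
            e = -np.log(pi)
            is_bound = np.array([macro.labels[a] == "bound"
                                 for a in macro.assignments])
            return cls(energies_kBT=e, bound=is_bound)
        lo, hi = group_label_ranges(memm.map.n_zbins)["bound"]
        zl = memm.map.z_label(memm.active_set)
        return cls(energies_kBT=memm.G / memm.kBT,
                   bound=(zl >= lo) & (zl <= hi))

    @classmethod
    def from_mix(cls, mix) -> "StateWeights":
        """Build from a constant-pH product-space model."""
        from .coarse import group_label_ranges
        lo, hi = group_label_ranges(mix.map.n_zbins)["bound"]
        zl = mix.z_labels()
        return cls(energies_kBT=mix.epsilon / mix.kBT,
                   bound=(zl >= lo) & (zl <= hi))


def partition_function(weights: StateWeights, conc_mM: float,
                       ref_conc_mM: float = 150.0) -> float:
    """Z(c) = sum_unbound e^-eps + (c/c_ref) sum_bound e^-eps."""
    w = np.exp(-(weights.energies_kBT - weights.energies_kBT.min()))
    if not weights.bound.any():
        raise ValueError("model exposes no ion-bound states")
    return float(w[~weights.bound].sum()
                 + (conc_mM / ref_conc_mM) * w[weights.bound].sum())


def partition_ratio(
    weights_inactive: StateWeights,
    weights_active: StateWeights,
    conc_grid_mM: np.ndarray,
    ref_conc_mM: float = 150.0,
) -> np.ndarray:
    """Z_inactive / Z_active on a concentration grid.

    The energy zero of each model is arbitrary; only the concentration
    dependence of the ratio matters downstream (rho normalizes at c = 0).
    """
    conc_grid_mM = np.asarray(conc_grid_mM, float)
    return np.array([
        partition_function(weights_inactive, c, ref_conc_mM)
        / partition_function(weights_active, c, ref_conc_mM)
        for c in conc_grid_mM
    ])


def rho_of_sodium(ratios: np.ndarray, ratio_at_zero: float) -> np.ndarray:
    """rho(c) = ratio(c)/ratio(0); rho(0) = 1 by construction."""
    if ratio_at_zero == 0 or not np.isfinite(ratio_at_zero):
        raise ValueError("reference ratio at zero sodium must be finite "
                         "and nonzero")
    return np.asarray(ratios, float) / ratio_at_zero


def ligand_l50(K_star_nM: float, tau_u: float, tau_b: float = 0.0) -> float:
    """L50 = K* (1 + tau_u)/(1 + tau_b) in nM."""
    if K_star_nM <= 0:
        raise ValueError("K* must be positive")
    if tau_u < 0 or tau_b < 0:
        raise ValueError("equilibrium constants must be >= 0")
    return K_star_nM * (1.0 + tau_u) / (1.0 + tau_b)


def bound_fraction(L_nM: float, L50_nM: float) -> float:
    """f_b = [L]/(L50 + [L])."""
    if L_nM < 0 or L50_nM < 0 or (L_nM == 0 and L50_nM == 0):
        raise ValueError("need non-negative L and L50, not both zero")
    return L_nM / (L50_nM + L_nM)


def percent_change_curve(x: float, rho: np.ndarray) -> np.ndarray:
    """Relative change of bound ligand, (1 - rho)/(x + rho).

    ``x`` is the ligand concentration over the zero-sodium L50 (default in
    the pipeline: 1 nM tracer over 4 nM affinity = 0.25).
    """
    rho = np.asarray(rho, float)
    if x <= 0:
        raise ValueError("x must be positive")
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    return (1.0 - rho) / (x + rho)


def sodium_ic50(
    conc_mM: np.ndarray,
    change: np.ndarray,
    level: float = 0.5,
    tol_mM: float = 0.1,
) -> float:
    """Sodium concentration at which binding is reduced by ``level``.

    Bisection on log concentration through the (monotone decreasing)
    percent-change curve, linearly interpolated between grid points.
    Raises :class:`NotReached` if the curve never reaches -level.
    """
    conc_mM = np.asarray(conc_mM, float)
    change = np.asarray(change, float)
    if np.any(np.diff(change) > 1e-12):
        raise ValueError("percent-change curve is not monotone decreasing")
    if change.min() > -level:
        raise NotReached(f"{level:.0%} reduction not reached on the grid "
                         f"(max reduction {-change.min():.1%})")
    logc = np.log(conc_mM)
    f = lambda lc: np.interp(lc, logc, change) + level
    lo, hi = logc[0], logc[-1]
    if f(lo) <= 0:
        return float(conc_mM[0])
    # bisection on log concentration; xtol chosen so the back-transformed
    # answer is within tol_mM
    x = brentq(f, lo, hi, xtol=min(1e-6, tol_mM / conc_mM[-1]))
    return float(np.exp(x))


@dataclass
class TwoStateReceptor:
    """Bundle of the allosteric prediction for one ligand.

    Carries the concentration grid, rho, and the percent-change curve; the
    activation free energy mu is optional and only needed to report the
    absolute active fraction f* = 1/(1 + e^mu Z_ina/Z_act).
    """

    conc_mM: np.ndarray
    rho: np.ndarray
    change: np.ndarray
    x: float
    K_star_nM: float
    ic50_mM: float | None = None
    change_lo: np.ndarray | None = None  # bootstrap quartile band
    change_hi: np.ndarray | None = None

    def to_table(self, path: str) -> None:
        cols = [self.conc_mM, self.rho, self.change]
        header = "conc_mM\trho\tpercent_change"
        if self.change_lo is not None:
            cols += [self.change_lo, self.change_hi]
            header += "\tchange_q1\tchange_q3"
        np.savetxt(path, np.column_stack(cols), delimiter="\t",
                   header=header, comments="")


def predict_modulation(
    weights_inactive: StateWeights,
    weights_active: StateWeights,
    conc_grid_mM: np.ndarray,
    ligand_conc_nM: float = 1.0,
    K_star_nM: float = 4.0,
    ref_conc_mM: float = 150.0,
    level: float = 0.5,
) -> TwoStateReceptor:
    """Full percent-change prediction from a pair of estimated models."""
    ratios = partition_ratio(weights_inactive, weights_active,
                             conc_grid_mM, ref_conc_mM)
    r0 = (partition_function(weights_inactive, 0.0, ref_conc_mM)
          / partition_function(weights_active, 0.0, ref_conc_mM))
    rho = rho_of_sodium(ratios, r0)
    x = ligand_conc_nM / K_star_nM
    change = percent_change_curve(x, rho)
    try:
        ic50 = sodium_ic50(conc_grid_mM, change, level=level)
    except NotReached as e:
        logger.info("IC50 not reached: %s", e)
        ic50 = None
    return TwoStateReceptor(conc_mM=np.asarray(conc_grid_mM, float),
                            rho=rho, change=change, x=x,
                            K_star_nM=K_star_nM, ic50_mM=ic50)
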