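"""Analytic 2D free-energy landscapes for the synthetic translocation system.

The synthetic system replaces atomistic trajectories of an ion crossing a
receptor with overdamped Brownian dynamics of two coordinates:

* ``z`` -- the translocation coordinate (angstrom), spanning the receptor from
  the cytoplasmic side (negative z) to the extracellular bulk (positive z);
* ``c`` -- a dimensionless slow conformational coordinate standing in for the
  collective protein motion that couples to ion binding.

Landscapes are sums of 2D Gaussian wells/barriers plus a harmonic confinement
of ``c``, so potentials, gradients and Boltzmann marginals are available in
closed form or by cheap quadrature.  Every landscape therefore carries an
analytically known 1D free-energy profile and oracle kinetics against which
the estimators in the rest of the package can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .constants import KBT_310

__all__ = [
    "GaussianTerm",
    "Landscape",
    "GroundTruth",
    "build_landscape",
    "two_well_landscape",
    "receptor_presets",
    "ground_truth_profile",
    "oracle_mfpt",
    "affinity_from_profile",
    "calibrate_depth_for_affinity",
]


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian well (negative amplitude) or barrier (positive amplitude).

    ``sigma_c = None`` makes the term independent of the conformational
    coordinate.
    """

    amplitude: float  # kcal/mol; <0 well, >0 barrier
    z0: float  # angstrom
    sigma_z: float  # angstrom
    c0: float = 0.0
    sigma_c: float | None = None

    def __post_init__(self) -> None:
        vals = [self.amplitude, self.z0, self.sigma_z, self.c0]
        if self.sigma_c is not None:
            vals.append(self.sigma_c)
        if not np.all(np.isfinite(vals)):
            raise ValueError("Gaussian term parameters must be finite")
        if self.sigma_z <= 0 or (self.sigma_c is not None and self.sigma_c <= 0):
            raise ValueError("Gaussian term widths must be positive (degenerate well)")

    def energy(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        arg = (np.asarray(z) - self.z0) ** 2 / (2.0 * self.sigma_z**2)
        if self.sigma_c is not None:
            arg = arg + (np.asarray(c) - self.c0) ** 2 / (2.0 * self.sigma_c**2)
        return self.amplitude * np.exp(-arg)

    def grad(self, z: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = self.energy(z, c)
        gz = e * -(np.asarray(z) - self.z0) / self.sigma_z**2
        if self.sigma_c is not None:
            gc = e * -(np.asarray(c) - self.c0) / self.sigma_c**2
        else:
            gc = np.zeros_like(e)
        return gz, gc


@dataclass(frozen=True)
class Landscape:
    """Analytic potential U(z, c) with diffusion constants and temperature.

    The conformational coordinate is harmonically confined,
    ``U_conf = 1/2 k_conf (c - c_conf)^2``, so the Boltzmann marginal over
    ``c`` is always integrable.
    """

    terms: tuple[GaussianTerm, ...] = ()
    k_conf: float = 1.0  # kcal/mol per unit c^2
    c_conf: float = 0.0
    z_range: tuple[float, float] = (-35.0, 40.0)
    D_z: float = 50.0  # A^2/ns
    D_c: float = 2.0  # 1/ns
    kBT: float = KBT_310  # kcal/mol
    variant: str = "charged"
    #: region of interest (umbrella-sampled pore); z_range may extend beyond
    #: it so the confining walls sit away from the scored region
    pore_range: tuple[float, float] | None = None
    #: one-sided harmonic wall stiffness beyond z_range (kcal/(mol A^2));
    #: keeps the ion confined without a hard boundary
    wall_k: float = 100.0

    @property
    def pore(self) -> tuple[float, float]:
        return self.pore_range if self.pore_range is not None else self.z_range

    def __post_init__(self) -> None:
        vals = [self.k_conf, self.c_conf, *self.z_range, self.D_z, self.D_c, self.kBT]
        if not np.all(np.isfinite(vals)):
            raise ValueError("landscape parameters must be finite")
        if self.k_conf <= 0:
            raise ValueError("k_conf must be positive for an integrable marginal")
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("empty z range")

    def potential(self, z, c):
        z = np.asarray(z, dtype=float)
        c = np.asarray(c, dtype=float)
        u = 0.5 * self.k_conf * (c - self.c_conf) ** 2
        u = u + np.zeros_like(z)
        lo, hi = self.z_range
        over = np.clip(z - hi, 0.0, None)
        under = np.clip(lo - z, 0.0, None)
        u = u + 0.5 * self.wall_k * (over**2 + under**2)
        for t in self.terms:
            u = u + t.energy(z, c)
        return u

    def grad(self, z, c):
        """Return (dU/dz, dU/dc) evaluated elementwise."""
        z = np.asarray(z, dtype=float)
        c = np.asarray(c, dtype=float)
        gz = np.zeros(np.broadcast(z, c).shape)
        gc = self.k_conf * (c - self.c_conf) + np.zeros_like(gz)
        lo, hi = self.z_range
        gz = gz + self.wall_k * (np.clip(z - hi, 0.0, None)
                                 - np.clip(lo - z, 0.0, None))
        for t in self.terms:
            tz, tc = t.grad(z, c)
            gz = gz + tz
            gc = gc + tc
        return gz, gc

    def marginal_free_energy(self, z, n_quad: int = 201, c_span: float = 8.0):
        """G(z) = -kBT ln ∫ exp(-U(z,c)/kBT) dc, not anchored.

        Quadrature over ``c_conf ± c_span`` standard spans of the confining
        well plus the offsets of any c-dependent Gaussian term.
        """
        z = np.atleast_1d(np.asarray(z, dtype=float))
        sigma_conf = np.sqrt(self.kBT / self.k_conf)
        c_lo = self.c_conf - c_span * sigma_conf
        c_hi = self.c_conf + c_span * sigma_conf
        for t in self.terms:
            if t.sigma_c is not None:
                c_lo = min(c_lo, t.c0 - c_span * t.sigma_c)
                c_hi = max(c_hi, t.c0 + c_span * t.sigma_c)
        cg = np.linspace(c_lo, c_hi, n_quad)
        u = self.potential(z[:, None], cg[None, :])
        u0 = u.min(axis=1, keepdims=True)
        w = np.exp(-(u - u0) / self.kBT)
        integral = np.trapezoid(w, cg, axis=1)
        return (u0[:, 0] - self.kBT * np.log(integral))


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference attached to a synthetic landscape."""

    z_centers: np.ndarray
    profile: np.ndarray  # G_true(z), kcal/mol, min anchored at 0
    density: np.ndarray  # normalized stationary density over the z bins
    kBT: float

    def barrier_between(self, z_a: float, z_b: float) -> float:
        """Height of the highest point of G_true between two z positions."""
        lo, hi = sorted((z_a, z_b))
        sel = (self.z_centers >= lo) & (self.z_centers <= hi)
        return float(self.profile[sel].max())


def build_landscape(
    wells: list[dict] | None = None,
    barriers: list[dict] | None = None,
    k_conf: float = 1.0,
    c_conf: float = 0.0,
    variant: str = "charged",
    neutral_offset: float = 3.0,
    **kwargs,
) -> Landscape:
    """Assemble a landscape from well/barrier parameter dicts.

    Each dict supplies ``depth`` (wells) or ``height`` (barriers) in kcal/mol
    together with ``z0``, ``sigma_z`` and optionally ``c0``/``sigma_c``.  The
    ``neutral`` variant raises every well by ``neutral_offset`` kcal/mol,
    emulating the shallower ion-binding well of the protonated (neutral)
    receptor form.
    """
    if variant not in ("charged", "neutral"):
        raise ValueError(f"unknown variant {variant!r}")
    terms = []
    for w in wells or []:
        depth = float(w["depth"])
        if depth > 0:
            raise ValueError("well depth must be <= 0")
        if variant == "neutral" and w.get("protonation_sensitive", True):
            depth = min(depth + neutral_offset, 0.0)
        terms.append(
            GaussianTerm(
                amplitude=depth,
                z0=float(w["z0"]),
                sigma_z=float(w["sigma_z"]),
                c0=float(w.get("c0", 0.0)),
                sigma_c=w.get("sigma_c"),
            )
        )
    for b in barriers or []:
        height = float(b["height"])
        if height < 0:
            raise ValueError("barrier height must be >= 0")
        terms.append(
            GaussianTerm(
                amplitude=height,
                z0=float(b["z0"]),
                sigma_z=float(b["sigma_z"]),
                c0=float(b.get("c0", 0.0)),
                sigma_c=b.get("sigma_c"),
            )
        )
    return Landscape(terms=tuple(terms), k_conf=k_conf, c_conf=c_conf, variant=variant, **kwargs)


def two_well_landscape(
    variant: str = "charged",
    bound_depth: float = -5.0,
    barrier_height: float = 4.0,
    ec_barrier_height: float = 2.5,
    vestibule_depth: float = -2.0,
    neutral_offset: float = 3.0,
    z_range: tuple[float, float] = (-10.0, 10.0),
    coupling: float = 0.0,
    wall_pad: float = 0.0,
    **kwargs,
) -> Landscape:
    """Desk-scale receptor analogue: bound well + cytoplasmic-side barrier.

    The geometry follows the z-bin label convention of the discretizer (100
    bins over the umbrella range): the bound well sits at the centre of the
    "bound" label range (bins 30-60), the barrier separates it from the
    cytoplasmic plateau (bins 1-10), and the extracellular plateau (bins
    90-100) is flat bulk.  ``coupling`` > 0 shifts the centre of the bound
    well in the conformational coordinate, creating a slow mode that only
    relaxes when the ion is bound.
    """
    lo, hi = z_range
    span = hi - lo
    z_bound = lo + 0.45 * span  # centre of bins 30-60
    z_barrier = lo + 0.13 * span  # just above the cytoplasmic range
    # a positive "depth" turns the site into a shallow repulsive bump, the
    # collapsed-site limit where the ion is locally disfavored; the bump is
    # broader than the well so it spans the whole bound band
    bound_key = "depth" if bound_depth <= 0 else "height"
    well = {bound_key: bound_depth, "z0": z_bound,
            "sigma_z": (0.06 if bound_depth <= 0 else 0.12) * span,
            "protonation_sensitive": True}
    if coupling > 0:
        well.update({"c0": coupling, "sigma_c": 1.0})
    # shallow vestibule at the receptor mouth (bins 90-100): a metastable
    # extracellular contact site, insensitive to the titratable residue
    vestibule = {"depth": vestibule_depth, "z0": lo + 0.945 * span,
                 "sigma_z": 0.02 * span, "protonation_sensitive": False}
    barriers = [{"height": barrier_height, "z0": z_barrier,
                 "sigma_z": 0.05 * span}]
    if ec_barrier_height > 0:
        barriers.append({"height": ec_barrier_height, "z0": lo + 0.80 * span,
                         "sigma_z": 0.04 * span})
    wells = [vestibule] if vestibule_depth < 0 else []
    if bound_key == "depth":
        wells.insert(0, well)
    else:
        barriers.append(well)
    return build_landscape(
        wells=wells,
        barriers=barriers,
        variant=variant,
        neutral_offset=neutral_offset,
        z_range=(lo - wall_pad, hi + wall_pad),
        pore_range=z_range,
        **kwargs,
    )


def receptor_presets(name: str = "smoke", **overrides) -> dict[str, Landscape]:
    """Charged/neutral landscape pairs used by the pipeline presets."""
    if name == "smoke":
        base = dict(z_range=(-10.0, 10.0), bound_depth=-5.0, barrier_height=4.0)
    elif name == "full":
        base = dict(z_range=(-35.0, 40.0), bound_depth=-5.0, barrier_height=4.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return {
        "charged": two_well_landscape(variant="charged", **base),
        "neutral": two_well_landscape(variant="neutral", **base),
    }


def ground_truth_profile(landscape: Landscape, bins: int = 500) -> GroundTruth:
    """Analytic 1D free-energy profile on a regular z grid, min anchored at 0."""
    if bins < 10:
        raise ValueError("need at least 10 bins")
    lo, hi = landscape.z_range
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    g = landscape.marginal_free_energy(centers)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-integrable potential")
    g = g - g.min()
    w = np.exp(-g / landscape.kBT)
    return GroundTruth(z_centers=centers, profile=g, density=w / w.sum(), kBT=landscape.kBT)


def oracle_mfpt(
    landscape: Landscape,
    source_region: tuple[float, float],
    target_region: tuple[float, float],
    bins: int = 1000,
) -> float:
    """Mean first passage time (ns) between z intervals on the marginal profile.

    Discretizes the 1D Smoluchowski operator on a fine grid as a
    nearest-neighbour Markov jump process with rates
    ``k(i -> i±1) = D_z/dz^2 * exp(-(G_{i±1}-G_i)/(2 kBT))`` and solves the
    absorbing-target linear system; the source average is Boltzmann-weighted
    over the source interval.
    """
    s_lo, s_hi = sorted(source_region)
    t_lo, t_hi = sorted(target_region)
    if s_hi <= s_lo or t_hi <= t_lo:
        raise ValueError("empty region")
    gt = ground_truth_profile(landscape, bins=bins)
    z, g = gt.z_centers, gt.profile
    in_src = (z >= s_lo) & (z <= s_hi)
    in_tgt = (z >= t_lo) & (z <= t_hi)
    if not in_src.any() or not in_tgt.any():
        raise ValueError("empty region after discretization")
    if (in_src & in_tgt).all() or np.array_equal(in_src, in_tgt):
        return 0.0
    dz = z[1] - z[0]
    base = landscape.D_z / dz**2
    n = len(z)
    up = base * np.exp(-(g[1:] - g[:-1]) / (2.0 * landscape.kBT))  # i -> i+1
    dn = base * np.exp(-(g[:-1] - g[1:]) / (2.0 * landscape.kBT))  # i+1 -> i
    # generator restricted to non-target states, absorbing target
    keep = ~in_tgt
    idx = -np.ones(n, dtype=int)
    idx[keep] = np.arange(keep.sum())
    K = np.zeros((keep.sum(), keep.sum()))
    diag = np.zeros(keep.sum())
    for i in range(n - 1):
        a, b = i, i + 1
        if keep[a]:
            diag[idx[a]] -= up[i]
            if keep[b]:
                K[idx[a], idx[b]] += up[i]
        if keep[b]:
            diag[idx[b]] -= dn[i]
            if keep[a]:
                K[idx[b], idx[a]] += dn[i]
    K[np.arange(keep.sum()), np.arange(keep.sum())] = diag
    m = np.linalg.solve(K, -np.ones(keep.sum()))
    src_keep = in_src & keep
    if not src_keep.any():
        return 0.0
    w = np.exp(-g[src_keep] / landscape.kBT)
    return float(np.dot(w, m[idx[src_keep]]) / w.sum())


def affinity_from_profile(
    z: np.ndarray,
    g: np.ndarray,
    bound_range: tuple[float, float],
    kBT: float,
    c_ref_mM: float = 150.0,
) -> float:
    """Equilibrium dissociation constant (mM) implied by a 1D profile.

    Using the grand-canonical convention of the allostery module, ion-bound
    configurations (z inside ``bound_range``) scale linearly with bulk
    concentration relative to the reference concentration at which the
    profile was sampled; Kd is the concentration at which bound and unbound
    statistical weights are equal: ``Kd = c_ref * W_unbound / W_bound``.
    """
    z = np.asarray(z, float)
    g = np.asarray(g, float)
    w = np.exp(-(g - g.min()) / kBT)
    in_bound = (z >= bound_range[0]) & (z <= bound_range[1])
    wb = w[in_bound].sum()
    wu = w[~in_bound].sum()
    if wb == 0:
        raise ValueError("no statistical weight in the bound range")
    return c_ref_mM * wu / wb


def calibrate_depth_for_affinity(
    target_kd_mM: float,
    bound_range: tuple[float, float] | None = None,
    c_ref_mM: float = 150.0,
    depth_bracket: tuple[float, float] = (-12.0, 8.0),
    **landscape_kwargs,
) -> Landscape:
    """Two-well landscape whose analytic sodium affinity equals ``target_kd_mM``.

    Solves for the bound-well depth by bisection on the analytic marginal
    profile.  ``bound_range`` defaults to the bound-label z window (bins
    30-60 of the umbrella range).
    """
    z_range = landscape_kwargs.get("z_range", (-10.0, 10.0))
    if bound_range is None:
        lo, hi = z_range
        bound_range = (lo + 0.29 * (hi - lo), lo + 0.60 * (hi - lo))

    def kd_of(depth: float) -> float:
        ls = two_well_landscape(bound_depth=depth, **landscape_kwargs)
        gt = ground_truth_profile(ls, bins=600)
        lo, hi = ls.pore
        sel = (gt.z_centers >= lo) & (gt.z_centers <= hi)
        return affinity_from_profile(gt.z_centers[sel], gt.profile[sel],
                                     bound_range, ls.kBT, c_ref_mM)

    f = lambda d: np.log(kd_of(d)) - np.log(target_kd_mM)
    depth = brentq(f, *depth_bracket, xtol=1e-6)
    return two_well_landscape(bound_depth=depth, **landscape_kwargs)
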