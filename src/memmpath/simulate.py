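"""Brownian-dynamics trajectory generator for the synthetic system.

Trajectories of the ion translocation coordinate ``z`` and the slow
conformational coordinate ``c`` are propagated by Metropolis-adjusted
overdamped Langevin dynamics on an analytic
:class:`~memmpath.landscape.Landscape`, either unbiased or under a harmonic
umbrella restraint on ``z``.  The
generator emulates the statistical structure of an umbrella-sampling
campaign: a ladder of windows spaced along z with a fixed force constant,
plus unbiased continuation runs started from the final frame of each window.

Determinism: a master seed is expanded into per-trajectory seeds with
``numpy.random.SeedSequence(master_seed).spawn`` in ladder order (the
documented counter scheme); identical seeds and parameters reproduce
trajectories bit-identically.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .landscape import Landscape

__all__ = [
    "EnsembleSpec",
    "Trajectory",
    "TrajectoryEnsemble",
    "window_ladder",
    "simulate_trajectory",
    "simulate_batch",
    "simulate_umbrella_campaign",
    "emit_features",
    "write_trajectories",
    "read_trajectories",
]

#: Maximum allowed deterministic drift per step, as a fraction of the
#: umbrella-window thermal width; larger steps raise (stability criterion).
MAX_DRIFT_PER_STEP_A = 0.5


@dataclass(frozen=True)
class EnsembleSpec:
    """Thermodynamic ensemble tag: unbiased, or harmonic umbrella on z.

    The flat-bottom cylindrical radius used in the emulated 3D setup is kept
    as inert metadata: with a single translocation coordinate there is no
    transverse escape for it to restrain.
    """

    kind: str  # "unbiased" | "umbrella"
    z0: float | None = None  # angstrom (umbrella centre)
    k_bias: float = 0.0  # kcal/(mol A^2)
    flat_bottom_radius: float | None = None  # angstrom, inert in 1D
    ensemble_id: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("unbiased", "umbrella"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.k_bias < 0:
            raise ValueError("k_bias must be >= 0")
        if self.kind == "umbrella" and (self.z0 is None or not np.isfinite(self.z0)):
            raise ValueError("umbrella ensemble requires a finite centre z0")

    def bias_energy(self, z: np.ndarray) -> np.ndarray:
        """Bias energy in kcal/mol at positions z."""
        if self.kind == "unbiased" or self.k_bias == 0.0:
            return np.zeros_like(np.asarray(z, dtype=float))
        return 0.5 * self.k_bias * (np.asarray(z, dtype=float) - self.z0) ** 2

    def bias_force(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "unbiased" or self.k_bias == 0.0:
            return np.zeros_like(np.asarray(z, dtype=float))
        return self.k_bias * (np.asarray(z, dtype=float) - self.z0)


@dataclass
class Trajectory:
    """One simulated trajectory: per-frame z, c and optional feature vectors."""

    z: np.ndarray
    c: np.ndarray
    dt: float  # ns between stored frames
    ensemble_id: int
    seed: int
    features: np.ndarray | None = None  # (n_frames, D)
    sensor_z: np.ndarray | None = None  # (D,) synthetic sensor positions

    def __len__(self) -> int:
        return len(self.z)

    @property
    def n_features(self) -> int:
        return 0 if self.features is None else self.features.shape[1]


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories plus the ensemble specifications they map to."""

    trajectories: list[Trajectory]
    specs: dict[int, EnsembleSpec]
    landscape: Landscape | None = None

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def n_frames(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def spec_of(self, traj: Trajectory) -> EnsembleSpec:
        return self.specs[traj.ensemble_id]

    def subset(self, kind: str) -> "TrajectoryEnsemble":
        keep = [t for t in self.trajectories if self.specs[t.ensemble_id].kind == kind]
        return TrajectoryEnsemble(keep, dict(self.specs), self.landscape)


def window_ladder(
    z_lo: float,
    z_hi: float,
    spacing: float = 0.5,
    k_bias: float = 10.0,
    flat_bottom_radius: float = 15.0,
    first_id: int = 0,
) -> list[EnsembleSpec]:
    """Umbrella windows uniformly spaced over [z_lo, z_hi].

    Defaults mirror the emulated campaign: 0.5 A spacing and a force constant
    of 10 kcal/(mol A^2); the window count follows from span/spacing + 1.
    """
    n = int(round((z_hi - z_lo) / spacing)) + 1
    centers = np.linspace(z_lo, z_hi, n)
    return [
        EnsembleSpec("umbrella", z0=float(z0), k_bias=k_bias,
                     flat_bottom_radius=flat_bottom_radius, ensemble_id=first_id + i)
        for i, z0 in enumerate(centers)
    ]


def _check_stability(landscape: Landscape, specs: list[EnsembleSpec], dt: float) -> None:
    lo, hi = landscape.z_range
    zg = np.linspace(lo, hi, 400)
    gz, gc = landscape.grad(zg, np.zeros_like(zg))
    max_force = np.abs(gz).max()
    k_max = max((s.k_bias for s in specs), default=0.0)
    # worst-case umbrella force within +-4 thermal widths of a window centre
    if k_max > 0:
        max_force += k_max * 4.0 * np.sqrt(landscape.kBT / k_max)
    drift = dt * max_force * landscape.D_z / landscape.kBT
    if drift > MAX_DRIFT_PER_STEP_A:
        raise ValueError(
            f"unstable step size: deterministic drift {drift:.3f} A/step exceeds "
            f"{MAX_DRIFT_PER_STEP_A} A; reduce dt below "
            f"{dt * MAX_DRIFT_PER_STEP_A / drift:.2e} ns"
        )


def simulate_batch(
    landscape: Landscape,
    specs: list[EnsembleSpec],
    n_steps: int,
    dt: float,
    seeds: list[int],
    z_init: np.ndarray | None = None,
    c_init: np.ndarray | None = None,
    stride: int = 1,
    equil_steps: int = 0,
) -> list[Trajectory]:
    """Propagate one trajectory per spec in lockstep (vectorized over specs).

    The propagator is Metropolis-adjusted overdamped Langevin (MALA): the
    Euler-Maruyama displacement serves as the proposal and a
    Metropolis-Hastings accept/reject step removes the finite-step-size
    bias, so the sampled stationary law is exactly the Boltzmann
    distribution of U + bias at any stable dt.  Rejected steps keep the
    current position; at the default step sizes the acceptance rate is
    above 95% and the dynamics remain diffusive.

    Per-trajectory noise streams come from independent Generators seeded
    with ``seeds``, so a batch run is bit-identical to the corresponding
    sequence of single-trajectory runs.
    """
    if n_steps < 0:
        raise ValueError("negative n_steps")
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_stability(landscape, specs, dt)
    m = len(specs)
    if len(seeds) != m:
        raise ValueError("one seed per spec required")
    lo, hi = landscape.z_range
    z = np.array(
        [s.z0 if (z_init is None and s.kind == "umbrella") else 0.0 for s in specs]
    ) if z_init is None else np.asarray(z_init, dtype=float).copy()
    if z_init is None:
        unb = np.array([s.kind == "unbiased" for s in specs])
        z[unb] = 0.5 * (lo + hi)
    c = (np.full(m, landscape.c_conf) if c_init is None
         else np.asarray(c_init, dtype=float).copy())
    k_b = np.array([s.k_bias if s.kind == "umbrella" else 0.0 for s in specs])
    z0_b = np.array([s.z0 if s.kind == "umbrella" else 0.0 for s in specs])

    gens = [np.random.default_rng(s) for s in seeds]
    noise = np.stack([g.standard_normal((n_steps, 2)) for g in gens], axis=1)
    unif = np.stack([g.random(n_steps) for g in gens], axis=1)

    amp_z = np.sqrt(2.0 * landscape.D_z * dt)
    amp_c = np.sqrt(2.0 * landscape.D_c * dt)
    fac_z = landscape.D_z * dt / landscape.kBT
    fac_c = landscape.D_c * dt / landscape.kBT
    kBT = landscape.kBT

    def drift(zz, cc):
        gz, gc = landscape.grad(zz, cc)
        gz = gz + k_b * (zz - z0_b)
        return zz - fac_z * gz, cc - fac_c * gc

    def energy(zz, cc):
        return (landscape.potential(zz, cc)
                + 0.5 * k_b * (zz - z0_b) ** 2)

    n_keep = (n_steps - equil_steps + stride - 1) // stride if n_steps > equil_steps else 0
    zs = np.empty((n_keep, m))
    cs = np.empty((n_keep, m))
    k = 0
    u = energy(z, c)
    mz, mc = drift(z, c)
    n_acc = 0
    for step in range(n_steps):
        zp = mz + amp_z * noise[step, :, 0]
        cp = mc + amp_c * noise[step, :, 1]
        up = energy(zp, cp)
        mzp, mcp = drift(zp, cp)
        log_q_fwd = -((zp - mz) ** 2) / (2 * amp_z**2) - ((cp - mc) ** 2) / (2 * amp_c**2)
        log_q_rev = -((z - mzp) ** 2) / (2 * amp_z**2) - ((c - mcp) ** 2) / (2 * amp_c**2)
        log_alpha = -(up - u) / kBT + log_q_rev - log_q_fwd
        acc = np.log(unif[step]) < log_alpha
        n_acc += int(acc.sum())
        z = np.where(acc, zp, z)
        c = np.where(acc, cp, c)
        u = np.where(acc, up, u)
        mz = np.where(acc, mzp, mz)
        mc = np.where(acc, mcp, mc)
        if step >= equil_steps and (step - equil_steps) % stride == 0:
            zs[k] = z
            cs[k] = c
            k += 1
    if n_steps:
        rate = n_acc / (n_steps * m)
        if rate < 0.9:
            warnings.warn(f"MALA acceptance rate {rate:.2f} below 0.9; "
                          "consider a smaller dt")
    return [
        Trajectory(z=zs[:, i].copy(), c=cs[:, i].copy(), dt=dt * stride,
                   ensemble_id=specs[i].ensemble_id, seed=int(seeds[i]))
        for i in range(m)
    ]


def simulate_trajectory(
    landscape: Landscape,
    spec: EnsembleSpec,
    n_steps: int,
    dt: float,
    seed: int,
    **kwargs,
) -> TrajectoryEnsemble:
    """Single-trajectory convenience wrapper around :func:`simulate_batch`."""
    trajs = simulate_batch(landscape, [spec], n_steps, dt, [seed], **kwargs)
    return TrajectoryEnsemble(trajs, {spec.ensemble_id: spec}, landscape)


def simulate_umbrella_campaign(
    landscape: Landscape,
    n_steps_window: int,
    n_steps_unbiased: int,
    dt: float,
    master_seed: int,
    spacing: float = 0.5,
    k_bias: float = 10.0,
    stride: int = 1,
    equil_steps: int = 0,
    margin: float = 0.0,
    unbiased_every: int = 1,
) -> TrajectoryEnsemble:
    """Window ladder over the z range plus unbiased continuation runs.

    Each umbrella window starts at its centre; each unbiased run continues
    from the final frame of every ``unbiased_every``-th window, mirroring the
    emulated campaign design.  All unbiased runs share ensemble id equal to
    the number of windows.  The ladder spans the landscape's pore range
    (the z domain may extend further so the reflecting walls sit away from
    the sampled region).
    """
    lo, hi = landscape.pore
    specs = window_ladder(lo + margin, hi - margin, spacing=spacing, k_bias=k_bias)
    nw = len(specs)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 * nw)
    w_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[:nw]]
    u_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[nw:]]

    window_trajs = simulate_batch(
        landscape, specs, n_steps_window, dt, w_seeds, stride=stride,
        equil_steps=equil_steps,
    )
    pick = list(range(0, nw, unbiased_every))
    unb_spec = EnsembleSpec("unbiased", ensemble_id=nw)
    unb_specs = [replace(unb_spec) for _ in pick]
    z_init = np.array([window_trajs[i].z[-1] for i in pick])
    c_init = np.array([window_trajs[i].c[-1] for i in pick])
    unb_trajs = simulate_batch(
        landscape, unb_specs, n_steps_unbiased, dt,
        [u_seeds[i] for i in pick], z_init=z_init, c_init=c_init, stride=stride,
    )
    all_specs = {s.ensemble_id: s for s in specs}
    all_specs[nw] = unb_spec
    return TrajectoryEnsemble(window_trajs + unb_trajs, all_specs, landscape)


def emit_features(
    trajs: TrajectoryEnsemble,
    D: int = 105,
    snr: float = 20.0,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Attach a D-dimensional feature vector to every frame.

    Features emulate inter-residue distance observables: smooth deterministic
    functions of (z, c) plus i.i.d. Gaussian noise of amplitude 1/snr.
    Feature 0 equals the conformational coordinate (so the slow mode is
    recoverable); the others are sigmoids of z centred on per-feature
    "sensor" positions spread along the pore, every third one with an
    additional loading on c.  Sensor positions are stored for the
    density-proximity feature pre-selection.
    """
    if D < 2:
        raise ValueError("need at least 2 features")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if trajs.landscape is None:
        raise ValueError("trajectory ensemble lacks a landscape reference")
    lo, hi = trajs.landscape.z_range
    sensors = np.linspace(lo, hi, D)
    width = 0.05 * (hi - lo)
    rng = np.random.default_rng(seed)
    out = []
    for t in trajs.trajectories:
        base = np.tanh((t.z[:, None] - sensors[None, 1:]) / width)
        cload = np.zeros(D - 1)
        cload[::3] = 0.5
        f = np.empty((len(t), D))
        f[:, 0] = t.c
        f[:, 1:] = base + t.c[:, None] * cload[None, :]
        f += rng.standard_normal(f.shape) / snr
        out.append(replace_features(t, f, sensors))
    return TrajectoryEnsemble(out, dict(trajs.specs), trajs.landscape)


def replace_features(t: Trajectory, features: np.ndarray, sensor_z: np.ndarray) -> Trajectory:
    return Trajectory(z=t.z, c=t.c, dt=t.dt, ensemble_id=t.ensemble_id,
                      seed=t.seed, features=features, sensor_z=sensor_z)


# ---------------------------------------------------------------------------
# flat-file I/O: one TSV per trajectory (time, z, c, features...) + YAML sidecar


def write_trajectories(trajs: TrajectoryEnsemble, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    meta = {"specs": {}, "trajectories": []}
    for eid, s in trajs.specs.items():
        meta["specs"][int(eid)] = {
            "kind": s.kind,
            "z0": None if s.z0 is None else float(s.z0),
            "k_bias": float(s.k_bias),
            "flat_bottom_radius": None if s.flat_bottom_radius is None
            else float(s.flat_bottom_radius),
        }
    for i, t in enumerate(trajs.trajectories):
        fname = f"traj_{i:04d}.tsv"
        n_feat = t.n_features
        cols = ["time_ns", "z_A", "c"] + [f"f{j}" for j in range(n_feat)]
        data = np.column_stack(
            [np.arange(len(t)) * t.dt, t.z, t.c]
            + ([t.features] if n_feat else [])
        )
        np.savetxt(os.path.join(outdir, fname), data,
                   header="\t".join(cols), delimiter="\t", comments="")
        meta["trajectories"].append({
            "file": fname, "ensemble_id": int(t.ensemble_id),
            "dt_ns": float(t.dt), "seed": int(t.seed),
            "sensor_z": None if t.sensor_z is None else [float(x) for x in t.sensor_z],
        })
    with open(os.path.join(outdir, "ensemble.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_trajectories(outdir: str) -> TrajectoryEnsemble:
    with open(os.path.join(outdir, "ensemble.yaml")) as fh:
        meta = yaml.safe_load(fh)
    specs = {
        int(eid): EnsembleSpec(kind=d["kind"], z0=d["z0"], k_bias=d["k_bias"],
                               flat_bottom_radius=d["flat_bottom_radius"],
                               ensemble_id=int(eid))
        for eid, d in meta["specs"].items()
    }
    trajs = []
    for rec in meta["trajectories"]:
        data = np.loadtxt(os.path.join(outdir, rec["file"]), skiprows=1)
        data = np.atleast_2d(data)
        features = data[:, 3:] if data.shape[1] > 3 else None
        trajs.append(Trajectory(
            z=data[:, 1], c=data[:, 2], dt=float(rec["dt_ns"]),
            ensemble_id=int(rec["ensemble_id"]), seed=int(rec["seed"]),
            features=features,
            sensor_z=None if rec["sensor_z"] is None else np.asarray(rec["sensor_z"]),
        ))
    return TrajectoryEnsemble(trajs, specs)
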