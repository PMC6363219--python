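"""End-to-end orchestration: synthetic campaign -> MEMM -> kinetics -> allostery.

A :class:`PipelineConfig` collects every tunable of the analysis with
defaults matching the emulated study design (100 z bins, tICA lag 0.1 ns,
TRAM lag 0.4 ns, 12 bootstrap samples at 90% of the unbiased frames,
correlation threshold 0.6, density factor 7 within 4.4 A, k_off = 1e6 1/s,
D_Na = 20 nm^2/us, r0 = 1.5 nm).  :func:`run_pipeline` executes the stages
for each configured receptor system, mixes the active-state protonation
variants into the constant-pH model, and produces the allosteric
modulation prediction; every artifact is written with the config hash and
seed, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import allostery, coarse, kinetics
from .constants import KBT_310
from .density import build_density_grid, profile_from_density, wham_weights
from .discretize import discretize_ensemble, window_convergence_score
from .landscape import (calibrate_depth_for_affinity, ground_truth_profile,
                        two_well_landscape)
from .simulate import emit_features, simulate_umbrella_campaign, write_trajectories
from .tica import correlate_features_to_tics, estimate_tica
from .tram import (bootstrap_resample, estimate_tram, free_energy_profile,
                   median_quartiles)

logger = logging.getLogger(__name__)

__all__ = ["SystemConfig", "PipelineConfig", "load_config", "save_config",
           "run_pipeline", "run_system"]


@dataclass
class SystemConfig:
    """One simulated receptor system (landscape variant + its estimators)."""

    variant: str = "charged"  # landscape variant
    bound_depth: float = -5.0  # kcal/mol; ignored if kd_target_mM is set
    barrier_height: float = 4.0  # kcal/mol
    kd_target_mM: float | None = None  # calibrate depth to this affinity
    n_clusters: int = 6  # conformational k-means clusters (N)
    n_pcca: int = 5  # metastable macrostates


def _default_systems() -> dict[str, SystemConfig]:
    # cluster counts follow the per-system defaults N = 6, 5, 4;
    # macrostate counts N_pcca = 9, 5, 7
    return {
        "inactive": SystemConfig(variant="charged", bound_depth=-6.5,
                                 n_clusters=6, n_pcca=9),
        "active_charged": SystemConfig(variant="charged", bound_depth=-4.0,
                                       n_clusters=5, n_pcca=5),
        "active_neutral": SystemConfig(variant="neutral", bound_depth=-4.0,
                                       n_clusters=4, n_pcca=7),
    }


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; defaults are the study conditions."""

    # landscape geometry
    z_range: tuple[float, float] = (-10.0, 10.0)
    coupling: float = 1.0
    neutral_offset: float = 3.0
    # campaign
    window_spacing: float = 0.5  # A
    k_bias: float = 10.0  # kcal/(mol A^2)
    n_steps_window: int = 300_000
    n_steps_unbiased: int = 120_000
    dt_ns: float = 1e-4
    stride: int = 50
    equil_steps: int = 10_000
    unbiased_every: int = 1
    # features / tICA
    n_features: int = 105
    feature_snr: float = 20.0
    tica_lag_ns: float = 0.1
    n_tics: int = 2
    corr_threshold: float = 0.6
    density_factor: float = 7.0
    density_cutoff_A: float = 4.4
    # discretization / MEMM
    n_zbins: int = 100
    tram_lag_ns: float = 0.4
    tram_tol: float = 1e-8
    tram_max_iter: int = 30_000
    relent_threshold: float = 0.2
    n_bootstrap: int = 0  # 12 for full error bars; 0 disables
    bootstrap_frac: float = 0.9
    # constant pH
    pKa: float = 9.0
    pH: float = 7.0
    k_off: float = 1e6  # 1/s
    # bulk kinetics
    D_Na: float = 20.0  # nm^2/us
    r_EC: float = 1.5  # nm
    gamma: str | float = "estimate"
    conc_grid_mM: tuple = (1.0, 3.0, 10.0, 30.0, 50.0, 100.0, 150.0, 300.0, 500.0, 1000.0)
    # allostery
    ligand_conc_nM: float = 1.0
    K_star_nM: float = 4.0
    ref_conc_mM: float = 150.0
    # systems and bookkeeping
    systems: dict = field(default_factory=_default_systems)
    seed: int = 0
    outdir: str = "memmpath_run"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def frame_dt_ns(self) -> float:
        return self.dt_ns * self.stride

    @property
    def tram_lag_frames(self) -> int:
        return max(1, int(round(self.tram_lag_ns / self.frame_dt_ns)))


_SMOKE_OVERRIDES = dict(
    window_spacing=1.0, k_bias=2.0, n_steps_window=30_000,
    n_steps_unbiased=30_000, dt_ns=2e-4, stride=10, equil_steps=3_000,
    unbiased_every=2,
    n_features=12, tram_max_iter=10_000,
    systems={
        "inactive": SystemConfig(variant="charged", bound_depth=-5.0,
                                 n_clusters=2, n_pcca=5),
        "active_charged": SystemConfig(variant="charged", bound_depth=-4.0,
                                       n_clusters=2, n_pcca=5),
        "active_neutral": SystemConfig(variant="neutral", bound_depth=-4.0,
                                       n_clusters=2, n_pcca=5),
    },
)


def preset_config(name: str = "default", **overrides) -> PipelineConfig:
    """Named presets: "default" (full study scale) or "smoke" (minutes)."""
    if name == "default":
        base = {}
    elif name == "smoke":
        base = dict(_SMOKE_OVERRIDES)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return PipelineConfig(**base)


def save_config(cfg: PipelineConfig, path: str) -> None:
    d = dataclasses.asdict(cfg)
    d["systems"] = {k: dataclasses.asdict(s) if dataclasses.is_dataclass(s)
                    else dict(s) for k, s in cfg.systems.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path: str) -> PipelineConfig:
    """Read and validate a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "systems" in raw and raw["systems"] is not None:
        sys_known = {f.name for f in dataclasses.fields(SystemConfig)}
        systems = {}
        for name, sd in raw["systems"].items():
            bad = set(sd) - sys_known
            if bad:
                raise ValueError(f"unknown keys in system {name!r}: {sorted(bad)}")
            systems[name] = SystemConfig(**sd)
        raw["systems"] = systems
    if "z_range" in raw:
        raw["z_range"] = tuple(raw["z_range"])
    if "conc_grid_mM" in raw:
        raw["conc_grid_mM"] = tuple(raw["conc_grid_mM"])
    return PipelineConfig(**raw)


def _build_landscape(cfg: PipelineConfig, sys_cfg: SystemConfig):
    common = dict(variant=sys_cfg.variant, barrier_height=sys_cfg.barrier_height,
                  neutral_offset=cfg.neutral_offset, z_range=cfg.z_range,
                  coupling=cfg.coupling)
    if sys_cfg.kd_target_mM is not None:
        return calibrate_depth_for_affinity(sys_cfg.kd_target_mM,
                                            c_ref_mM=cfg.ref_conc_mM, **common)
    return two_well_landscape(bound_depth=sys_cfg.bound_depth, **common)


def run_system(cfg: PipelineConfig, name: str, seed: int,
               outdir: str | None = None) -> dict:
    """Simulate and estimate one receptor system; returns its artifacts."""
    sys_cfg = cfg.systems[name]
    ls = _build_landscape(cfg, sys_cfg)
    logger.info("[%s] simulating campaign (seed %d)", name, seed)
    trajs = simulate_umbrella_campaign(
        ls, n_steps_window=cfg.n_steps_window,
        n_steps_unbiased=cfg.n_steps_unbiased, dt=cfg.dt_ns,
        master_seed=seed, spacing=cfg.window_spacing, k_bias=cfg.k_bias,
        stride=cfg.stride, equil_steps=cfg.equil_steps,
        unbiased_every=cfg.unbiased_every)
    trajs = emit_features(trajs, D=cfg.n_features, snr=cfg.feature_snr,
                          seed=seed + 1)

    # window convergence report
    relent = {}
    for t in trajs:
        if trajs.specs[t.ensemble_id].kind == "umbrella":
            score, ok = window_convergence_score(
                t.z, threshold=cfg.relent_threshold)
            relent[t.ensemble_id] = (score, ok)

    logger.info("[%s] tICA + discretization", name)
    tica = estimate_tica(trajs, lag_ns=cfg.tica_lag_ns, n_components=cfg.n_tics)
    tics = tica.project_ensemble(trajs)
    selection = correlate_features_to_tics(trajs, tica,
                                           threshold=cfg.corr_threshold)
    data = discretize_ensemble(trajs, tics, n_zbins=cfg.n_zbins,
                               n_clusters=sys_cfg.n_clusters, kBT=ls.kBT,
                               seed=seed)

    # 1D WHAM density profile over the z bins (equilibrium check on TRAM)
    zb = [np.clip(np.searchsorted(data.map.z_edges, t.z, side="right") - 1,
                  0, cfg.n_zbins - 1) for t in trajs]
    bias_zb = np.stack([
        trajs.specs[eid].bias_energy(
            0.5 * (data.map.z_edges[:-1] + data.map.z_edges[1:])) / ls.kBT
        for eid in sorted(trajs.specs)])
    wham = wham_weights([np.asarray(b) for b in zb],
                        [sorted(trajs.specs).index(t.ensemble_id) for t in trajs],
                        bias_zb)

    logger.info("[%s] TRAM estimation (lag %d frames)", name,
                cfg.tram_lag_frames)
    memm = estimate_tram(data, lag=cfg.tram_lag_frames, tol=cfg.tram_tol,
                         max_iter=cfg.tram_max_iter, dt_ns=cfg.frame_dt_ns,
                         kBT=ls.kBT)
    profile = free_energy_profile(memm)

    boot_memms = []
    if cfg.n_bootstrap > 0:
        for bi, btraj in enumerate(bootstrap_resample(
                trajs, n_samples=cfg.n_bootstrap, frac=cfg.bootstrap_frac,
                seed=seed + 100)):
            bdata = discretize_ensemble(
                btraj, [tica.transform(t.features) for t in btraj],
                n_zbins=cfg.n_zbins, n_clusters=sys_cfg.n_clusters,
                kBT=ls.kBT, seed=seed)
            boot_memms.append(estimate_tram(
                bdata, lag=cfg.tram_lag_frames, tol=max(cfg.tram_tol, 1e-7),
                max_iter=cfg.tram_max_iter, dt_ns=cfg.frame_dt_ns, kBT=ls.kBT))
        profs = [free_energy_profile(b).G for b in boot_memms] + [profile.G]
        stack = np.vstack(profs)
        med = np.median(stack, axis=0)
        q1 = np.percentile(stack, 25, axis=0)
        q3 = np.percentile(stack, 75, axis=0)
        profile.err_lo = med - q1
        profile.err_hi = q3 - med

    macro = coarse.build_macrostate_model(memm, sys_cfg.n_pcca)

    # capture probability from the unbiased runs
    lo, hi = cfg.z_range
    span = hi - lo
    z_mouth = lo + 0.89 * span  # inner edge of the extracellular band
    z_bind = lo + 0.60 * span  # outer edge of the bound band
    unb = [t.z for t in trajs
           if trajs.specs[t.ensemble_id].kind == "unbiased"]
    if cfg.gamma == "estimate":
        try:
            gamma = kinetics.estimate_capture_probability(
                unb, z_mouth=z_mouth, z_bind=z_bind)
        except ValueError:
            logger.warning("[%s] no encounter events; gamma set to 1", name)
            gamma = 1.0
    else:
        gamma = float(cfg.gamma)

    out = {
        "landscape": ls, "trajs": trajs, "tica": tica, "selection": selection,
        "wham": wham, "data": data, "memm": memm, "profile": profile,
        "macro": macro, "gamma": gamma, "relent": relent,
        "ground_truth": ground_truth_profile(ls, bins=cfg.n_zbins),
        "boot_memms": boot_memms,
    }
    if outdir is not None:
        _write_system(cfg, name, out, outdir)
    return out


def _write_system(cfg, name, res, outdir):
    d = os.path.join(outdir, name)
    os.makedirs(d, exist_ok=True)
    res["profile"].to_table(os.path.join(d, "profile.tsv"))
    res["selection"].to_table(os.path.join(d, "feature_selection.tsv"))
    res["tica"].save(os.path.join(d, "tica_model.tsv"))
    grid = build_density_grid(
        np.concatenate([t.z for t in res["trajs"]])[:, None],
        np.concatenate(res["wham"].sample_weights(
            *_wham_args(cfg, res))),
        extent=(cfg.z_range[1] - cfg.z_range[0],), spacing=0.25,
        origin=(cfg.z_range[0],))
    np.savetxt(os.path.join(d, "density_profile.tsv"),
               profile_from_density(grid, res["landscape"].kBT),
               delimiter="\t",
               header="z_center\tdensity_nm3\tnormalized\tG_kcal_mol",
               comments="")
    with open(os.path.join(d, "macrostates.tsv"), "w") as fh:
        fh.write("macrostate\tlabel\tpi\n")
        for a, (lb, p) in enumerate(zip(res["macro"].labels,
                                        res["macro"].pi_coarse)):
            fh.write(f"{a}\t{lb}\t{p:.6e}\n")


def _wham_args(cfg, res):
    trajs = res["trajs"]
    data = res["data"]
    zb = [np.clip(np.searchsorted(data.map.z_edges, t.z, side="right") - 1,
                  0, cfg.n_zbins - 1) for t in trajs]
    bias_zb = np.stack([
        trajs.specs[eid].bias_energy(
            0.5 * (data.map.z_edges[:-1] + data.map.z_edges[1:]))
        / res["landscape"].kBT
        for eid in sorted(trajs.specs)])
    ids = [sorted(trajs.specs).index(t.ensemble_id) for t in trajs]
    return zb, ids, bias_zb


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage for all systems plus the cross-system analyses."""
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    save_config(cfg, os.path.join(outdir, "config.yaml"))
    provenance = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    results = {}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31))
             for c in ss.spawn(len(cfg.systems))]
    for (name, _), seed in zip(cfg.systems.items(), seeds):
        try:
            results[name] = run_system(cfg, name, seed, outdir=outdir)
        except Exception as e:
            raise RuntimeError(f"pipeline stage failed in system {name!r}: {e}"
                               ) from e

    summary = {"provenance": provenance, "systems": {}}
    for name, res in results.items():
        memm = res["memm"]
        summary["systems"][name] = {
            "n_active_microstates": int(memm.n_states),
            "tram_converged": bool(memm.converged),
            "gamma": float(res["gamma"]),
            "macrostate_labels": list(res["macro"].labels),
        }

    # constant-pH mix of the active variants
    conc = np.asarray(cfg.conc_grid_mM, float)
    if {"active_charged", "active_neutral"} <= set(results):
        try:
            mix = kinetics.mix_protonation_states(
                results["active_charged"]["memm"],
                results["active_neutral"]["memm"],
                pKa=cfg.pKa, pH=cfg.pH, k_off=cfg.k_off)
        except ValueError as e:
            raise RuntimeError(f"pipeline stage failed in constant-pH mixing: {e}"
                               ) from e
        results["mix"] = mix
        summary["mix"] = {"delta_G0_kcal_mol": float(mix.delta_G0)}

    # concentration-dependent kinetics per system
    for name, res in list(results.items()):
        if name == "mix":
            continue
        ck = kinetics.coarse_kinetics_from_macrostates(res["macro"])
        if len(ck.states_in_group("bound")) == 0 or \
                len(ck.states_in_group("extracellular")) == 0:
            logger.warning("[%s] missing bound/extracellular macrostates; "
                           "kinetics skipped", name)
            continue
        scan = kinetics.concentration_kinetics(
            ck, conc, D_nm2_us=cfg.D_Na, r_EC_nm=cfg.r_EC,
            gamma=res["gamma"])
        res["kinetics"] = scan
        scan.to_table(os.path.join(outdir, name, "kinetics.tsv"))
        summary["systems"][name]["affinity_mM"] = (
            None if scan.affinity_mM is None else float(scan.affinity_mM))

    # concentration kinetics of the constant-pH mixed model
    if "mix" in results and {"active_charged", "active_neutral"} <= set(results):
        try:
            ck_mix = kinetics.aggregate_mix_to_groups(
                results["mix"],
                results["active_charged"]["macro"],
                results["active_neutral"]["macro"],
                results["active_charged"]["memm"],
                results["active_neutral"]["memm"])
            if (len(ck_mix.states_in_group("bound"))
                    and len(ck_mix.states_in_group("extracellular"))):
                scan = kinetics.concentration_kinetics(
                    ck_mix, conc, D_nm2_us=cfg.D_Na, r_EC_nm=cfg.r_EC,
                    gamma=results["active_charged"]["gamma"])
                results["mix_kinetics"] = scan
                scan.to_table(os.path.join(outdir, "mix_kinetics.tsv"))
                summary["mix"]["affinity_mM"] = (
                    None if scan.affinity_mM is None
                    else float(scan.affinity_mM))
            else:
                logger.warning("mixed model lacks bound/extracellular "
                               "groups; kinetics skipped")
        except ValueError as e:
            logger.warning("mixed-model kinetics failed: %s", e)

    # allosteric prediction: inactive vs the constant-pH active model
    if "inactive" in results and "mix" in results:
        w_ina = allostery.StateWeights.from_memm(
            results["inactive"]["memm"], macro=results["inactive"]["macro"])
        w_act = allostery.StateWeights.from_mix(results["mix"])
        pred = allostery.predict_modulation(
            w_ina, w_act, conc, ligand_conc_nM=cfg.ligand_conc_nM,
            K_star_nM=cfg.K_star_nM, ref_conc_mM=cfg.ref_conc_mM)
        results["modulation"] = pred
        pred.to_table(os.path.join(outdir, "modulation.tsv"))
        summary["modulation"] = {
            "ic50_mM": None if pred.ic50_mM is None else float(pred.ic50_mM),
            "x": float(pred.x),
        }

    with open(os.path.join(outdir, "summary.yaml"), "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    results["summary"] = summary
    return results
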