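"""Coarse-grained kinetics: macrostates, MFPTs and concentration scans.

Starting from a fitted microstate model, this groups microstates into
metastable macrostates (PCCA+), projects the transition matrix onto them
(Hummer-Szabo), labels them cytoplasmic / bound / extracellular by the
90% rule, couples the chain to bulk reservoirs with the Smoluchowski
encounter rate, and prints binding / dissociation / egress times across
sodium concentrations.
"""

import numpy as np

from memmpath import coarse, kinetics
from memmpath.discretize import discretize_ensemble
from memmpath.landscape import two_well_landscape
from memmpath.simulate import simulate_umbrella_campaign
from memmpath.tram import estimate_tram

landscape = two_well_landscape(variant="charged", coupling=1.0)
trajs = simulate_umbrella_campaign(
    landscape, n_steps_window=60_000, n_steps_unbiased=120_000, dt=1e-4,
    master_seed=13, spacing=1.0, k_bias=10.0, stride=25, equil_steps=5_000,
    unbiased_every=1)
tics = [t.c[:, None] for t in trajs]
data = discretize_ensemble(trajs, tics, n_zbins=50, n_clusters=2, seed=0)
memm = estimate_tram(data, lag=80, tol=1e-7, max_iter=20_000, dt_ns=0.0025)

macro = coarse.build_macrostate_model(memm, n_macro=5)
print("macrostate  label           pi")
for a, (lb, p) in enumerate(zip(macro.labels, macro.pi_coarse)):
    print(f"{a:10d}  {lb:14s}  {p:.4f}")

gamma = kinetics.estimate_capture_probability(
    [t.z for t in trajs if trajs.specs[t.ensemble_id].kind == "unbiased"],
    z_mouth=7.8, z_bind=2.0)
print(f"\ncapture probability gamma = {gamma:.3f} "
      "(fraction of pore entries that reach the binding site)")

ck = kinetics.coarse_kinetics_from_macrostates(macro)
scan = kinetics.concentration_kinetics(
    ck, np.array([10.0, 50.0, 150.0, 500.0]), D_nm2_us=20.0, r_EC_nm=1.5,
    gamma=gamma)
print("\n[Na+] mM  binding_ns  dissociation_ns  egress_ns  occupancy")
for c, b, d, e, o in zip(scan.conc_mM, scan.binding_ns,
                         scan.dissociation_ns, scan.egress_ns,
                         scan.occupancy):
    print(f"{c:8.0f}  {b:10.3g}  {d:15.4g}  {e:9.3g}  {o:9.3f}")
print(f"\nbinding affinity (50% occupancy): {scan.affinity_mM:.1f} mM")
print("Binding accelerates linearly with concentration (diffusion-limited")
print("encounter) while dissociation is concentration-independent.  Egress")
print("still shows residual dependence at this compressed synthetic scale:")
print("rebinding after an extracellular excursion is not yet negligible")
print("compared to the cytoplasmic exit time.")
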