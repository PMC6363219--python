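"""Estimate the translocation free-energy profile with TRAM.

Runs a reduced umbrella + unbiased campaign, discretizes the frames into
(z-bin x conformational-cluster) microstates and solves the multi-ensemble
TRAM equations.  The integrated profile G(z) is printed against the
analytic ground truth of the generating landscape.
"""

import numpy as np

from memmpath.discretize import discretize_ensemble
from memmpath.landscape import ground_truth_profile, two_well_landscape
from memmpath.simulate import simulate_umbrella_campaign
from memmpath.tram import estimate_tram, free_energy_profile

landscape = two_well_landscape(variant="charged", coupling=1.0)
trajs = simulate_umbrella_campaign(
    landscape, n_steps_window=60_000, n_steps_unbiased=60_000, dt=1e-4,
    master_seed=3, spacing=1.0, k_bias=10.0, stride=25, equil_steps=5_000,
    unbiased_every=2)

# the conformational coordinate plays the role of the tICA projection here
tics = [t.c[:, None] for t in trajs]
data = discretize_ensemble(trajs, tics, n_zbins=50, n_clusters=2, seed=0)
memm = estimate_tram(data, lag=80, tol=1e-7, max_iter=20_000, dt_ns=0.0025)
profile = free_energy_profile(memm)

gt = ground_truth_profile(landscape, bins=400)
g_true = np.interp(profile.z_centers, gt.z_centers, gt.profile)

print(f"TRAM: {memm.n_states} active microstates, converged after "
      f"{memm.n_iter} iterations\n")
print("   z_A   G_est  G_true   (kcal/mol)")
for i in range(0, 50, 4):
    print(f"{profile.z_centers[i]:6.1f}  {profile.G[i]:6.2f}  "
          f"{g_true[i]:6.2f}")

sel = np.isfinite(profile.G)
rms = np.sqrt(np.mean((profile.G[sel] - g_true[sel]) ** 2))
print(f"\nRMS deviation from the analytic profile: {rms:.2f} kcal/mol.")
print("The bound well (~z = -1) and both barriers are recovered from the")
print("biased + unbiased data jointly; no single ensemble samples the")
print("whole coordinate on its own.")
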