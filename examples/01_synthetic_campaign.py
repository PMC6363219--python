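"""Generate a small umbrella-sampling campaign on a two-well landscape.

Builds the charged-variant receptor analogue (bound well -5 kcal/mol,
cytoplasmic barrier +4), runs a ladder of harmonic windows plus unbiased
continuation runs, and prints per-window convergence scores next to the
analytic profile values at the window centres.
"""

import numpy as np

from memmpath.discretize import window_convergence_score
from memmpath.landscape import ground_truth_profile, two_well_landscape
from memmpath.simulate import simulate_umbrella_campaign

landscape = two_well_landscape(variant="charged", coupling=1.0)
gt = ground_truth_profile(landscape, bins=400)

trajs = simulate_umbrella_campaign(
    landscape,
    n_steps_window=30_000, n_steps_unbiased=30_000,
    dt=2e-4, master_seed=7,
    spacing=1.0, k_bias=10.0, stride=10, equil_steps=3_000,
    unbiased_every=4,
)

n_windows = sum(1 for s in trajs.specs.values() if s.kind == "umbrella")
print(f"{len(trajs)} trajectories ({n_windows} umbrella windows + "
      f"{len(trajs) - n_windows} unbiased runs), {trajs.n_frames} frames\n")
print("window  centre_A  mean_z   G_true  relent  converged")
for t in trajs:
    spec = trajs.specs[t.ensemble_id]
    if spec.kind != "umbrella" or t.ensemble_id % 4:
        continue
    score, ok = window_convergence_score(t.z, threshold=0.2)
    g = np.interp(spec.z0, gt.z_centers, gt.profile)
    print(f"{t.ensemble_id:6d}  {spec.z0:8.1f}  {np.mean(t.z):6.2f}  "
          f"{g:7.2f}  {score:6.3f}  {ok}")

print("\nEach window's mean position sits near its restraint centre (pulled")
print("slightly toward low free energy); a relative-entropy score below 0.2")
print("means the window's first and second halves sample the same histogram,")
print("the stop criterion used when extending umbrella windows.")
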