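# Methods

This note documents the models and estimators implemented in `memmpath`,
the parameter choices that matter, and what the synthetic validation does
and does not demonstrate.

## The synthetic system

The generator replaces atomistic trajectories with overdamped Brownian
dynamics of two coordinates: the ion translocation coordinate `z` (Å) and
a dimensionless conformational coordinate `c` standing in for the slow
collective protein motion that couples to ion binding.  Landscapes are
sums of 2D Gaussian wells and barriers plus a harmonic confinement of
`c`, so the potential, its gradient and the Boltzmann marginal
`G_true(z) = −kBT ln ∫ e^{−U(z,c)/kBT} dc` are available analytically (the
marginal by 1D quadrature).  The receptor-like preset places

* a bound well (default −5 kcal/mol) at the centre of the bound z-label
  band, optionally shifted in `c` (`coupling`) so the conformational mode
  only relaxes when the ion is bound;
* a +4 kcal/mol barrier toward the cytoplasmic side and a +2.5 kcal/mol
  barrier toward the extracellular side (the dissociation pathway);
* a −2 kcal/mol extracellular vestibule, insensitive to the protonation
  variant, giving the receptor mouth a genuine metastable contact site;
* stiff one-sided harmonic walls (100 kcal/(mol·Å²)) at the edges of the
  umbrella-sampled range, entering the potential (and hence the analytic
  marginal) like any other term; wall-lip excursions are thin (~0.08 Å)
  and brief.

A positive "bound depth" turns the site into a shallow repulsive bump —
the collapsed-site limit used when calibrating very weak affinities.
The `neutral` variant raises the bound well by a stated offset (default
+3 kcal/mol), emulating the weaker ion binding of the protonated residue.

**Propagator.** The trajectory sampler is Metropolis-adjusted Langevin
(MALA): the Euler–Maruyama displacement is the proposal and a
Metropolis–Hastings accept/reject step makes the sampled stationary law
exactly the Boltzmann distribution of `U + bias` at any stable step size.
Plain Euler–Maruyama was evaluated first; its O(dt) stationary bias near
barriers accumulates across the umbrella-window ladder into a systematic
tilt of the reconstructed profile of several tenths of a kcal/mol, which
the Metropolis correction removes by construction.  Rejected steps keep
the current position; at the default `dt = 1e-4 ns` the acceptance rate
exceeds 95% and the dynamics remain diffusive (the small rejection
fraction rescales effective diffusion, which is irrelevant to the
thermodynamic targets and immaterial to the qualitative kinetic checks).

Defaults: `kBT = 0.616 kcal/mol` (310 K), `D_z = 50 Å²/ns` (an ion inside
a protein, a few-fold below bulk), `D_c = 2 /ns` with unit confinement
stiffness, giving a conformational relaxation time of ~0.3 ns — two and a
half orders of magnitude slower than the thermal relaxation of `z` inside
one umbrella window, so tICA has a genuinely slow mode to find.  Seeds:
one master seed expanded with `numpy.random.SeedSequence(...).spawn` in
ladder order; identical seeds reproduce trajectories bit-identically.

**Campaign design.**  Umbrella windows every 0.5 Å at 10 kcal/(mol·Å²)
across the pore, each started at its window centre, with an unbiased
continuation run launched from the final frame of each window.  The
default window length is 30 ns (validation runs use 25 ns) with 12 ns
unbiased continuations; window convergence is monitored with the
symmetrized relative entropy between first- and second-half histograms
(accept below 0.2).  These lengths sit inside the emulated campaign's
envelope (windows extended up to 100 ns until converged) and were chosen
so the window-to-window linkage noise — a random walk along the ladder
that dominates the profile error — stays well inside the validation
tolerance.  The flat-bottom cylindrical restraint of the emulated 3D
setup is carried as inert metadata: with a single translocation
coordinate there is no transverse escape for it to restrain.

## Estimators

**tICA.**  Reversible (forward/backward symmetrized) time-lagged
covariances pooled over all trajectories — biased and unbiased alike,
matching how the conformational landscape is used downstream — with a
1e-10 ridge on the instantaneous covariance for degenerate features.
Components are normalized to unit training variance and sign-fixed so the
largest-magnitude loading is positive.  Default lag 0.1 ns, two retained
components.  Feature selection takes |Pearson r| > 0.6 against the
retained components over pooled frames (the frame set is a choice; pooled
is used for consistency with the landscape construction).

**WHAM.**  Standard self-consistent histogram iteration in log space over
per-(ensemble, bin) bias energies; tolerance 1e-8 kBT on the shifts, at
most 100,000 iterations; the first ensemble's shift anchors the gauge.
Empty bins are excluded from normalization and reported as zero density
(+∞ free energy).  Disconnected histogram support across ensembles is a
hard error naming the separated windows.  Density grids are weighted
voxel counts divided by voxel volume (particles/nm³), normalized to the
mean over a designated bulk region (default: the outermost 10% of the
last axis on the extracellular side, occupied voxels only).

**TRAM.**  The discrete transition-based reweighting estimator over
microstates `(z-bin, cluster)` (100 z bins over the umbrella range ×
k-means clusters in tIC space; ids enumerate the product, reports use
1-based z labels).  Per ensemble k the model couples a reversible
transition-matrix likelihood on the lag-τ counts with a local-equilibrium
reweighting of every sample under every ensemble's bias; the
self-consistent equations for the Lagrange multipliers ν, the
normalization factors R and the biased free energies f are iterated in
log space (see the module docstring for the update formulas).  Details:

* **Initialization** from a WHAM solve on the per-state mean biases,
  which lands f near the fixed point and roughly halves the iteration
  count.
* **Truncation:** ensembles whose bias on a frame exceeds 50 kBT are
  dropped from that frame's reweighting sums (their Boltzmann factors are
  below 1e-21); far (ensemble, state) pairs carry a sentinel free energy.
  The truncated solution is numerically identical to the dense one.
* The inner loop is a numba kernel over the sparse transition-pair
  structure with streaming log-sum-exp reductions.
* **Connectivity:** the active set is the largest component connected by
  transitions in any ensemble and restricted to visited states.  The
  kinetic model is further restricted to the largest component connected
  by *unbiased* transitions — states only reachable through biased runs
  carry no unbiased kinetics and would otherwise appear as absorbing
  self-loops; the outgoing deficit folds into the diagonal, preserving
  detailed balance.
* **Outputs:** π from the unbiased-state free energies; T with
  symmetric-flux off-diagonals (exactly reversible w.r.t. π) and diagonal
  completion to row-stochasticity; convergence on max |Δf| (default
  1e-8), sliding-window counting, default lag 0.4 ns.
* With a single unbiased ensemble the fixed point coincides with the
  reversible MSM maximum-likelihood estimator to machine precision (this
  is asserted in the tests).  The TRAM log-likelihood rises to its
  terminal maximum; on multi-ensemble data the coupled update can show
  transient dips of order 1e-5 relative, so strict per-iteration
  monotonicity is only asserted for the single-ensemble case.

Discretization details that matter near the boundary: frames outside the
binned range are dropped and the trajectory is **split at the gap** —
splicing the remainder together would fabricate transitions across the
excursion — and frames within 0.5 Å beyond the range (snapshots caught on
the confining wall) are clipped into the edge bins while keeping their
true per-frame bias.  Dropping those lip frames instead was measured to
censor the lag-window transition statistics near the boundary and bias
edge free energies upward by several tenths of a kcal/mol over one
diffusion length per lag.

Profiles integrate the cluster dimension by log-sum-exp (min-anchored;
unpopulated bins report +∞).  Errors come from whole-trajectory bootstrap
of the unbiased data (12 samples at 90% of the unbiased frames, umbrella
set kept; summaries are the median over samples plus the full estimate
with 1st/3rd-quartile errors).  Bootstrap models reuse the full-sample
microstate definition, since re-clustering would change state identity.

**Coarse graining.**  PCCA+ in the inner-simplex form on the dominant
eigenvectors of the π-symmetrized kinetic matrix (memberships clipped to
the simplex and row-normalized; degeneracy at the spectral gap is
reported and broken by index).  The Hummer–Szabo projection uses the
discrete fundamental matrix: with aggregation matrix M, Π = diag(π),
π̂ = M'π and Z = (I − T + 1π')⁻¹,

    Ẑ = diag(π̂)⁻¹ M' Π Z M,      T̂ = I + 1π̂' − Ẑ⁻¹,

which preserves π̂ exactly and returns the exact lumped chain for
lumpable inputs.  The projection uses the *crisp* (argmax) memberships:
with fuzzy memberships on chains containing diffusive, weakly metastable
stretches the overlap matrix becomes ill-conditioned and the projected
matrix acquires large negative entries; crisp aggregation keeps any
negativity at round-off level, and whatever remains is clipped with a
warning before the rate-matrix conversion `K = (T − I)/τ` (valid for lags
well below the relaxation times; a matrix logarithm can produce negative
rates).  Macrostates are labeled by the 90% rule over the group z-label
ranges (cytoplasmic 1–10, bound 30–60, extracellular 90–100 on 100 bins;
other bin counts scale the same fractions), with π-weighted microstate
fractions by default — unpopulated microstates carry no kinetic meaning —
and a crisp-count alternative by flag.  Unmatched macrostates remain
explicit intermediates.  MFPTs solve the absorbing-target linear system
with stationary-weighted sources; unreachable targets report infinity.

## Constant-pH mixing

The titratable site is charged (α) or neutral (β); each variant has its
own estimated model sharing the microstate map.  The protonation shift
`ΔG₀ = kBT ln10 (pKa − pH)` (2.84 kcal/mol at pKa 9, pH 7, 310 K) is
applied to the charged block after both blocks are re-anchored so their
extracellular-plateau free energy is zero — the reference state with the
ion far from the site, where the pKa is defined.  The product-space rate
matrix takes within-protonation rates from each model's `(T − I)/τ` and
switches protonation only at fixed `(z, i)`: deprotonation at the
constant rate k_off (default 1e6 /s) and protonation at
`k_off · exp((ε_α − ε_β)/kBT)` with the per-state shifted energies, which
makes the product chain exactly reversible with respect to Boltzmann(ε).
Writing the protonation rate with the z-resolved charged probability
`p_α(z)` instead (the rate `k_off e^{ΔG(z)/kBT}` with
`p_α ≡ e^{−ΔG/kBT}`) agrees with this per-state form only in the limit of
a dominant protonation state and does *not* satisfy detailed balance in
general; the detailed-balance form is used so that the combined
stationary distribution is the Boltzmann law of the combined energies and
the z-marginal charged probability is exactly
`p_α(z) = 1/(1 + e^{(ε_α(z) − ε_β(z))/kBT})`.  Macro-level rates
aggregate the product chain by stationary-flux averages
`K_ab = Σ_{i∈a,j∈b} π_i K_ij / Σ_{i∈a} π_i` (the normalized form of the
population-weighted sum).

## Bulk coupling and concentration dependence

The coarse receptor chain is wired to an extracellular reservoir through
the Smoluchowski encounter rate `k₊ = 4πD r [Na⁺]` (D = 20 nm²/µs,
r = r₀ = 1.5 nm by default — the encounter radius is identified with the
cylinder radius since nothing relates them otherwise), distributed over
the extracellular-group states by their stationary weights.  Escape rates
follow from the capture probability γ: the default *flux form*
`γ = Σ k_in/(k_esc + Σ k_in)` gives `k_esc = (1−γ)/γ · Σ k_in`; the
as-printed alternative with the escape rate in the numerator is exposed
behind a flag.  γ can be supplied or estimated by counting, over the
unbiased trajectories, the fraction of inward mouth crossings that reach
the binding depth before recrossing the mouth (episodes re-arm only after
the ion returns outside; zero observed captures yield a half-count upper
bound so the estimate stays positive).  No binding flux enters from the
intracellular side: the intracellular bulk is absorbing.

Binding is the MFPT from the extracellular bulk to the bound group;
dissociation from the bound group (stationary-weighted) to the
extracellular bulk; egress to the intracellular bulk.  Binding and
dissociation are evaluated with the (much slower) intracellular leak
closed — with a competing absorbing sink every expectation would be
formally infinite.  The equilibrium occupancy closes the intracellular
side, solves the stationary distribution, and reports the bound-group
weight; the binding affinity is the concentration at 50% occupancy by
bisection on log concentration.  On a two-state toy this reproduces
`Kd = k₋(1−γ)/(k₊γ)` exactly.  Note the affinity of the *synthetic*
kinetic network depends on the γ-based escape normalization — it is a
property of the assembled kinetic model, not of the landscape alone; the
landscape-level affinity used for calibration is the grand-canonical one
below.

## Two-state allosteric model

Only the ratio ρ enters the predictions, so the activation free energy μ
is never required (it cancels; it is exposed only for reporting the
absolute active fraction).  Partition functions use grand-canonical
weighting of the ion-bound states: `Z(c) = Σ_unbound e^{−ε} +
(c/c_ref) Σ_bound e^{−ε}` with c_ref the simulated concentration
(150 mM); bound states are the bound-group macrostates when a coarse
model is available, otherwise the bound z-label band.  This choice
reproduces two-state binding isotherms exactly on toys.  The percent
change of bound agonist is `(1−ρ)/(x+ρ)` at `x = [L]/L₅₀(0)` (default
1 nM / 4 nM = 0.25), and the reported IC50 solves a 50% reduction by
bisection on log concentration (tolerance 0.1 mM).  For the constant-pH
active model the mixed product-space energies enter Z directly.

Affinity calibration: a landscape's analytic sodium affinity is defined
through the same convention, `Kd = c_ref · W_unbound/W_bound` with the
Boltzmann weights of the marginal profile split at the bound z band; a
bisection on the bound-site depth (well or bump) sets any target Kd.

## Validation scales and what they show

The full-scale checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use 41 umbrella windows (0.5 Å spacing,
10 kcal/(mol·Å²)) of 25 ns each plus 41 unbiased 12 ns continuations,
two conformational clusters, TRAM at lag 0.4 ns — roughly 3×10⁵ frames
per system, a few minutes of CPU per estimate.  The calibrated-affinity
comparison (IC50 against the analytic toy) uses the canonical two-well
geometry without the labeling vestibule — its statistical weight is
irrelevant to the isotherm and it concentrates ladder-linkage noise into
a few bins — and softer restraints (2.5 kcal/(mol·Å²), window width equal
to the spacing), which densify the window overlap and roughly halve the
linkage noise of the integrated bound/unbound weights.  Under these conditions
the TRAM profile reproduces the analytic two-well landscape to
~0.1–0.2 kcal/mol RMS (tolerance 0.3), and the end-to-end pipeline on
landscapes calibrated to 23 mM / 850 mM affinities recovers the analytic
toy's modulation IC50 within 25%.  Estimator identities (TRAM = reversible
MSM on one ensemble, detailed balance, Hummer–Szabo exactness, closed-form
MFPTs and the allosteric arithmetic) hold to near machine precision.

What passing these tests shows: the estimator chain is internally
consistent and statistically efficient on data whose generating law is
known exactly.  What it does not show: robustness to the failure modes of
real molecular simulations — force-field error, hidden slow degrees of
freedom beyond the one modelled coordinate, non-Markovianity at the
chosen lag, discretization of a genuinely high-dimensional conformational
space, or under-converged umbrella windows.  The synthetic feature noise
is i.i.d. Gaussian; real distance observables have correlated,
state-dependent noise.

## Known limitations

* The kinetic network's binding affinity depends on the encounter-escape
  normalization (γ); absolute synthetic affinities from the network are
  model quantities, while calibrated comparisons use the grand-canonical
  landscape affinity.
* Egress times can retain concentration dependence when rebinding after
  an extracellular excursion is not fast compared to the cytoplasmic exit
  (visible at the compressed synthetic scales; negligible in the regime
  the model targets, where binding is ns–µs and egress seconds).
* The Hummer–Szabo projection of weakly metastable chains requires crisp
  aggregation and may still need round-off clipping.
* `K = (T − I)/τ` underestimates rates approaching the lag timescale.
* PCCA+ splits of diffusive regions are seed- and data-dependent; group
  labels can come out unassigned on sparse data (reported, not fatal).
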