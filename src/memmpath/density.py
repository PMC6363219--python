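"""WHAM reweighting and bulk-normalized density grids (OpenDX export).

The weighted histogram analysis method (WHAM) combines histograms collected
under several biased ensembles into a single unbiased probability per bin by
self-consistent iteration over per-ensemble free-energy shifts f_k:

    p_i  =  sum_k n_{ki}  /  sum_k N_k exp(f_k - b_{ki})
    f_k  = -ln sum_i p_i exp(-b_{ki})

with n_{ki} the histogram counts, N_k the ensemble sample totals and b_{ki}
the bias energy (in kBT) of ensemble k evaluated in bin i.  The resulting
per-sample weights feed a rectangular density grid (1-3 axes) whose values
are number densities in particles/nm^3, normalized to the mean density of a
designated bulk region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .constants import NM3_IN_A3

__all__ = [
    "WhamResult",
    "DensityGrid",
    "wham_weights",
    "build_density_grid",
    "write_dx_grid",
    "read_dx_grid",
    "profile_from_density",
]

logger = logging.getLogger(__name__)


@dataclass
class WhamResult:
    """Self-consistent WHAM solution over a shared binning."""

    probabilities: np.ndarray  # (n_bins,) unbiased p_i, sums to 1 on support
    shifts: np.ndarray  # (n_ensembles,) f_k in kBT, first ensemble anchored at 0
    converged: bool
    n_iter: int
    increment_trace: np.ndarray  # max |delta f_k| per iteration
    log_likelihood_trace: np.ndarray | None = None

    def sample_weights(self, dtrajs: list[np.ndarray],
                       ensemble_ids: list[int],
                       bias: np.ndarray) -> list[np.ndarray]:
        """Unbiased per-frame weights mu(x) for samples binned as in the fit.

        mu(x) = p_{i(x)} / sum_k N_k exp(f_k - b_k(i(x))) is constant within
        a bin; weights are returned unnormalized per frame and can be pooled.
        """
        counts = _histogram(dtrajs, ensemble_ids, bias.shape[1])
        N_k = counts.sum(axis=1)
        log_denom = logsumexp(
            np.log(N_k)[:, None] + self.shifts[:, None] - bias, axis=0)
        with np.errstate(divide="ignore"):
            log_mu_bin = np.where(self.probabilities > 0,
                                  -log_denom, -np.inf)
        return [np.exp(log_mu_bin[d]) for d in dtrajs]


def _histogram(dtrajs, ensemble_ids, n_bins):
    K = max(ensemble_ids) + 1
    counts = np.zeros((K, n_bins))
    for d, k in zip(dtrajs, ensemble_ids):
        counts[k] += np.bincount(d, minlength=n_bins)
    return counts


def _check_overlap(counts: np.ndarray) -> None:
    """Fail loudly if the ensembles do not share histogram support."""
    K = counts.shape[0]
    adj = np.zeros((K, K), dtype=bool)
    occupied = counts > 0
    for k in range(K):
        adj[k] = (occupied[k][None, :] & occupied).any(axis=1)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        bad = [int(k) for k in np.flatnonzero(labels != labels[0])]
        raise ValueError(
            f"no histogram overlap between ensembles; disconnected windows {bad}")


def wham_weights(
    dtrajs_binned: list[np.ndarray],
    ensemble_ids: list[int],
    bias_energies: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> WhamResult:
    """Self-consistent WHAM estimate of unbiased bin probabilities.

    Parameters
    ----------
    dtrajs_binned
        One integer bin-index series per trajectory.
    ensemble_ids
        Ensemble index of each trajectory (0-based, contiguous).
    bias_energies
        (n_ensembles, n_bins) bias energy of each ensemble evaluated at each
        bin centre, in kBT units; must be finite.
    """
    bias = np.asarray(bias_energies, float)
    if not np.all(np.isfinite(bias)):
        raise ValueError("bias energies must be finite")
    K, n_bins = bias.shape
    for d in dtrajs_binned:
        if d.min() < 0 or d.max() >= n_bins:
            raise ValueError("bin index out of range")
    counts = _histogram(dtrajs_binned, ensemble_ids, n_bins)
    if counts.shape[0] != K:
        raise ValueError("ensemble ids exceed bias matrix rows")
    _check_overlap(counts)
    N_k = counts.sum(axis=1)
    M_i = counts.sum(axis=0)
    support = M_i > 0
    log_Mi = np.where(support, np.log(np.where(support, M_i, 1.0)), -np.inf)
    log_Nk = np.where(N_k > 0, np.log(np.where(N_k > 0, N_k, 1.0)), -np.inf)

    f = np.zeros(K)
    trace = []
    ll_trace = []
    converged = False
    for it in range(max_iter):
        # log p_i = log M_i - logsumexp_k [log N_k + f_k - b_ki]
        log_p = log_Mi - logsumexp(log_Nk[:, None] + f[:, None] - bias, axis=0)
        f_new = -logsumexp(log_p[None, :] - bias, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f)) if it > 0 else np.inf
        trace.append(delta)
        f = f_new
        # WHAM log-likelihood (up to data-dependent constants); uses the
        # normalized probabilities with matching un-anchored shifts
        log_p_norm = log_p - logsumexp(log_p[support])
        f_ll = -logsumexp(log_p_norm[None, :] - bias, axis=1)
        ll_trace.append(float(np.sum(M_i[support] * log_p_norm[support])
                              + np.sum(N_k * f_ll)))
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("WHAM did not converge in %d iterations", max_iter)
    log_p = log_Mi - logsumexp(log_Nk[:, None] + f[:, None] - bias, axis=0)
    p = np.exp(log_p - logsumexp(log_p[support]))
    p[~support] = 0.0
    return WhamResult(probabilities=p, shifts=f, converged=converged,
                      n_iter=len(trace), increment_trace=np.asarray(trace),
                      log_likelihood_trace=np.asarray(ll_trace))


@dataclass
class DensityGrid:
    """Rectangular number-density grid over 1-3 axes.

    ``values`` are particles/nm^3; ``normalized`` divides by the mean value
    over the designated bulk region (normalization constant ``bulk_density``).
    Origin sits at the lower corner; voxel (i,j,k) covers the half-open cell
    origin + [i, i+1) * spacing per axis.
    """

    origin: np.ndarray  # (ndim,) angstrom
    spacing: np.ndarray  # (ndim,) angstrom
    values: np.ndarray  # number density, particles/nm^3
    bulk_density: float  # particles/nm^3
    normalized: np.ndarray

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def dims(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_points(self) -> int:
        return int(self.values.size)


def build_density_grid(
    positions: np.ndarray,
    weights: np.ndarray | None,
    extent: tuple,
    spacing,
    bulk_region: tuple | None = None,
    origin=None,
) -> DensityGrid:
    """Weighted density histogram over a rectangular grid.

    ``extent`` gives the length of each axis in angstrom; the number of grid
    points per axis is extent/spacing (which must divide evenly).  Weighted
    counts per voxel are divided by the voxel volume and converted to
    particles/nm^3.  ``bulk_region`` is a (lo, hi) tuple per axis (use None
    per axis for "whole range"); it defaults to the outermost 10% of the last
    axis at the high end, the extracellular side in the pipeline's
    orientation.
    """
    pos = np.atleast_2d(np.asarray(positions, float))
    if pos.shape[0] == 1 and pos.shape[1] > 1 and np.ndim(extent) == 0:
        pos = pos.T
    extent = np.atleast_1d(np.asarray(extent, float))
    ndim = len(extent)
    if pos.shape[1] != ndim:
        raise ValueError("positions do not match grid dimensionality")
    spacing = np.broadcast_to(np.asarray(spacing, float), (ndim,)).copy()
    dims = extent / spacing
    dims_i = np.round(dims).astype(int)
    if not np.allclose(dims, dims_i, atol=1e-9):
        raise ValueError("spacing must divide extent on every axis")
    origin = (np.zeros(ndim) if origin is None
              else np.broadcast_to(np.asarray(origin, float), (ndim,)).copy())
    w = np.ones(len(pos)) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    idx = np.floor((pos - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < dims_i), axis=1)
    flat = np.ravel_multi_index(tuple(idx[inside].T), tuple(dims_i))
    hist = np.bincount(flat, weights=w[inside], minlength=int(np.prod(dims_i)))
    hist = hist.reshape(tuple(dims_i))
    voxel_nm3 = float(np.prod(spacing)) / NM3_IN_A3
    values = hist / voxel_nm3

    if bulk_region is None:
        lo = origin[-1] + 0.9 * extent[-1]
        bulk_region = tuple([None] * (ndim - 1) + [(lo, origin[-1] + extent[-1])])
    mask = np.ones(values.shape, dtype=bool)
    for ax, sel in enumerate(bulk_region):
        if sel is None:
            continue
        centers = origin[ax] + (np.arange(dims_i[ax]) + 0.5) * spacing[ax]
        ax_mask = (centers >= sel[0]) & (centers <= sel[1])
        shape = [1] * ndim
        shape[ax] = dims_i[ax]
        mask &= ax_mask.reshape(shape)
    if not mask.any():
        raise ValueError("empty bulk region")
    occupied = values > 0
    bulk_vals = values[mask & occupied]
    if bulk_vals.size == 0 or bulk_vals.mean() == 0:
        raise ValueError("zero bulk density; cannot normalize")
    bulk = float(values[mask][values[mask] > 0].mean())
    return DensityGrid(origin=origin, spacing=spacing, values=values,
                       bulk_density=bulk, normalized=values / bulk)


def profile_from_density(grid: DensityGrid, kBT: float) -> np.ndarray:
    """1D profile table (z_center, density, normalized, G) from a 1D grid.

    Free energies are -kBT ln(normalized density); empty voxels get +inf.
    """
    if grid.ndim != 1:
        raise ValueError("profile export requires a 1D grid")
    z = grid.origin[0] + (np.arange(grid.dims[0]) + 0.5) * grid.spacing[0]
    with np.errstate(divide="ignore"):
        g = np.where(grid.normalized > 0,
                     -kBT * np.log(np.where(grid.normalized > 0,
                                            grid.normalized, 1.0)),
                     np.inf)
    finite = np.isfinite(g)
    if finite.any():
        g = g - g[finite].min()
    return np.column_stack([z, grid.values, grid.normalized, g])


def write_dx_grid(grid: DensityGrid, path: str, normalized: bool = False) -> None:
    """Write a 3D grid as an OpenDX scalar field file."""
    if grid.ndim != 3:
        raise ValueError("OpenDX export requires a 3D grid")
    nx, ny, nz = grid.dims
    data = (grid.normalized if normalized else grid.values).ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {grid.spacing[1]:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {grid.spacing[2]:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {data.size} "
                 "data follows\n")
        for i in range(0, data.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in data[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_dx_grid(path: str) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`write_dx_grid`."""
    counts = None
    origin = np.zeros(3)
    deltas = []
    data: list[float] = []
    n_items = 0
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "object" and "gridpositions" in line:
                counts = tuple(int(x) for x in tok[-3:])
            elif tok[0] == "origin":
                origin = np.array([float(x) for x in tok[1:4]])
            elif tok[0] == "delta":
                deltas.append([float(x) for x in tok[1:4]])
            elif tok[0] == "object" and "data follows" in line:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items and len(data) < n_items:
                try:
                    data.extend(float(x) for x in tok)
                except ValueError:
                    pass
    if counts is None or len(data) < n_items:
        raise ValueError(f"{path} is not a readable OpenDX grid")
    spacing = np.array([deltas[i][i] for i in range(3)])
    values = np.array(data[:n_items]).reshape(counts, order="C")
    occ = values > 0
    bulk = float(values[occ].mean()) if occ.any() else 1.0
    return DensityGrid(origin=origin, spacing=spacing, values=values,
                       bulk_density=bulk, normalized=values / bulk)
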