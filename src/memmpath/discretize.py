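"""Microstate discretization: z-bins x conformational clusters.

Markov-model microstates combine (i) the ion position along the pore,
divided into ``n_zbins`` bins (default 100) over the umbrella-sampled range,
with (ii) a k-means clustering of the slow conformational space (tIC
coordinates).  Microstate ids enumerate the (z_bin, cluster) product;
reports use the 1-based z-bin labels 1..100 so the macrostate grouping
ranges (cytoplasmic 1-10, bound 30-60, extracellular 90-100) read the same
way as in the kinetics module.

Also here: splitting of trajectories at periodic-boundary crossings, the
per-frame bias-energy matrix required by TRAM, and the relative-entropy
convergence score for umbrella windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .simulate import EnsembleSpec, Trajectory, TrajectoryEnsemble

__all__ = [
    "MicrostateMap",
    "DiscreteTrajectories",
    "split_on_boundary_crossings",
    "cluster_tic_space",
    "assign_microstates",
    "compute_bias_energies",
    "window_convergence_score",
    "discretize_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass
class MicrostateMap:
    """Bijective index over (z bin, conformational cluster) pairs."""

    z_edges: np.ndarray  # (n_zbins + 1,), strictly increasing
    cluster_centers: np.ndarray  # (n_clusters, d) in tIC space

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.z_edges) > 0):
            raise ValueError("z bin edges must be strictly increasing")
        self.cluster_centers = np.atleast_2d(self.cluster_centers)

    @property
    def n_zbins(self) -> int:
        return len(self.z_edges) - 1

    @property
    def n_clusters(self) -> int:
        return self.cluster_centers.shape[0]

    @property
    def n_microstates(self) -> int:
        return self.n_zbins * self.n_clusters

    def index(self, z_bin: np.ndarray, cluster: np.ndarray) -> np.ndarray:
        """0-based microstate id from 0-based (z_bin, cluster)."""
        return np.asarray(z_bin) * self.n_clusters + np.asarray(cluster)

    def unindex(self, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        state = np.asarray(state)
        return state // self.n_clusters, state % self.n_clusters

    def z_label(self, state: np.ndarray) -> np.ndarray:
        """1-based z-bin label (1..n_zbins) of each microstate id."""
        return self.unindex(state)[0] + 1

    def z_center(self, state: np.ndarray) -> np.ndarray:
        zb = self.unindex(state)[0]
        return 0.5 * (self.z_edges[zb] + self.z_edges[zb + 1])


@dataclass
class DiscreteTrajectories:
    """TRAM-ready discrete data: microstate series + full bias matrix."""

    dtrajs: list[np.ndarray]  # per-frame microstate id
    ensemble_ids: list[int]  # one per trajectory, 0-based contiguous
    bias: np.ndarray  # (n_ensembles, n_total_frames) in kBT
    traj_slices: list[slice]  # frame span of each trajectory in bias columns
    map: MicrostateMap
    n_dropped: int = 0

    @property
    def n_ensembles(self) -> int:
        return self.bias.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bias.shape[1]

    def microstate_counts(self) -> np.ndarray:
        counts = np.zeros(self.map.n_microstates)
        for d in self.dtrajs:
            counts += np.bincount(d, minlength=self.map.n_microstates)
        return counts


def split_on_boundary_crossings(z: np.ndarray, box_length: float) -> list[np.ndarray]:
    """Split a z series wherever it jumps across the periodic boundary.

    A jump with |dz| > box_length/2 between consecutive frames is treated as
    a wrap-around; the series is cut there so no artificial transition links
    the two sides of the box.  Frames are conserved: segment lengths sum to
    the input length and segment count = crossings + 1.
    """
    if box_length <= 0:
        raise ValueError("box length must be positive")
    z = np.asarray(z)
    if len(z) < 2:
        return [z]
    jumps = np.flatnonzero(np.abs(np.diff(z)) > box_length / 2.0)
    return np.split(z, jumps + 1)


def cluster_tic_space(
    tic_coords: list[np.ndarray] | np.ndarray,
    k: int,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """k-means (k-means++ init, fixed seed) on pooled tIC coordinates.

    Returns the cluster centres and per-trajectory assignment series.
    Assignment is by nearest centre with ties broken toward the lowest
    cluster index.
    """
    if isinstance(tic_coords, np.ndarray):
        tic_coords = [tic_coords]
    X = np.concatenate([np.atleast_2d(np.asarray(t, float).T).T for t in tic_coords])
    if X.ndim == 1:
        X = X[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(X) < k:
        raise ValueError(f"cannot place {k} clusters on {len(X)} frames")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed).fit(X)
    centers = km.cluster_centers_
    assigns = []
    for t in tic_coords:
        tt = np.asarray(t, float)
        if tt.ndim == 1:
            tt = tt[:, None]
        d2 = ((tt[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assigns.append(np.argmin(d2, axis=1))  # argmin takes the lowest index on ties
    return centers, assigns


def assign_microstates(
    z_series: list[np.ndarray],
    cluster_series: list[np.ndarray],
    smap: MicrostateMap,
) -> tuple[list[list[np.ndarray]], int]:
    """Combine z-bin and cluster series into microstate id series.

    Frames with z outside the binning range are dropped (count returned and
    logged) and the trajectory is split at the gaps -- splicing the
    remainder together would fabricate transitions across the excursion.
    Returns one list of contiguous segments per input trajectory.  The z
    bin is found on the map's edges with half-open intervals, the last bin
    closed.
    """
    out = []
    dropped = 0
    lo, hi = smap.z_edges[0], smap.z_edges[-1]
    for z, cl in zip(z_series, cluster_series):
        z = np.asarray(z, float)
        cl = np.asarray(cl)
        keep = (z >= lo) & (z <= hi)
        dropped += int((~keep).sum())
        segments = []
        for run in np.split(np.arange(len(z)), np.flatnonzero(np.diff(keep)) + 1):
            if len(run) == 0 or not keep[run[0]]:
                continue
            zb = np.clip(np.searchsorted(smap.z_edges, z[run], side="right") - 1,
                         0, smap.n_zbins - 1)
            segments.append(smap.index(zb, cl[run]))
        out.append(segments)
    if dropped:
        logger.info("dropped %d out-of-range frames during assignment "
                    "(trajectories split at the gaps)", dropped)
    return out, dropped


def compute_bias_energies(
    trajs: TrajectoryEnsemble,
    kBT: float,
    ensemble_order: list[int] | None = None,
) -> tuple[np.ndarray, list[int], list[slice]]:
    """Bias energy of every frame under every ensemble, in kBT units.

    Returns (bias matrix (K, n_frames), per-trajectory ensemble index into
    the matrix rows, per-trajectory frame slices).  Unbiased ensembles
    contribute a zero row; umbrella ensembles 1/2 k (z - z0)^2 / kBT.  TRAM
    needs the bias of each frame under *all* ensembles, not only the one it
    was sampled in.
    """
    order = sorted(trajs.specs) if ensemble_order is None else list(ensemble_order)
    row_of = {eid: r for r, eid in enumerate(order)}
    missing = {t.ensemble_id for t in trajs} - set(order)
    if missing:
        raise ValueError(f"missing ensemble specs for ids {sorted(missing)}")
    n_frames = trajs.n_frames
    bias = np.zeros((len(order), n_frames))
    slices = []
    ens_ids = []
    at = 0
    z_all = np.concatenate([t.z for t in trajs])
    for t in trajs:
        slices.append(slice(at, at + len(t)))
        ens_ids.append(row_of[t.ensemble_id])
        at += len(t)
    for r, eid in enumerate(order):
        bias[r] = trajs.specs[eid].bias_energy(z_all) / kBT
    return bias, ens_ids, slices


def window_convergence_score(
    window_z: np.ndarray,
    n_bins: int = 50,
    threshold: float = 0.2,
    min_frames: int = 10,
) -> tuple[float, bool]:
    """Symmetrized KL divergence between first- and second-half histograms.

    Used as the stop/accept criterion for umbrella windows: a window is
    accepted when the score drops below ``threshold`` (default 0.2).  An
    add-one pseudo-count on bins occupied by either half regularizes empty
    bins.
    """
    z = np.asarray(window_z, float)
    if len(z) < 2 * min_frames:
        raise ValueError(f"window needs at least {2 * min_frames} frames")
    half = len(z) // 2
    lo, hi = z.min(), z.max()
    if lo == hi:
        return 0.0, True
    edges = np.linspace(lo, hi, n_bins + 1)
    h1, _ = np.histogram(z[:half], bins=edges)
    h2, _ = np.histogram(z[half:2 * half], bins=edges)
    occ = (h1 + h2) > 0
    if not occ.any():
        raise ValueError("empty histogram support")
    p = h1[occ] + 1.0
    q = h2[occ] + 1.0
    p = p / p.sum()
    q = q / q.sum()
    score = float(0.5 * np.sum(p * np.log(p / q)) + 0.5 * np.sum(q * np.log(q / p)))
    return score, score < threshold


def discretize_ensemble(
    trajs: TrajectoryEnsemble,
    tic_series: list[np.ndarray],
    n_zbins: int = 100,
    n_clusters: int = 6,
    kBT: float | None = None,
    seed: int = 0,
    z_range: tuple[float, float] | None = None,
    clip_tol: float = 0.5,
) -> DiscreteTrajectories:
    """End-to-end discretization of a trajectory ensemble.

    z bins cover the umbrella-sampled range (or ``z_range``); the
    conformational space is clustered with k-means on the supplied tIC
    series (one per trajectory, aligned with ``trajs``).  Frames within
    ``clip_tol`` angstrom beyond the range (brief excursions onto the
    confining wall) are clipped into the edge bins -- dropping them would
    censor the transition statistics near the boundary -- while frames
    further out are dropped and the trajectory split at the gap.  Bias
    energies always use the true frame positions.
    """
    if kBT is None:
        if trajs.landscape is None:
            raise ValueError("kBT required when the ensemble has no landscape")
        kBT = trajs.landscape.kBT
    if z_range is None:
        centers = [s.z0 for s in trajs.specs.values() if s.kind == "umbrella"]
        if centers:
            z_range = (min(centers), max(centers))
        elif trajs.landscape is not None:
            z_range = trajs.landscape.z_range
        else:
            z_all = np.concatenate([t.z for t in trajs])
            z_range = (float(z_all.min()), float(z_all.max()))
    edges = np.linspace(z_range[0], z_range[1], n_zbins + 1)
    centers_km, assigns = cluster_tic_space(tic_series, k=n_clusters, seed=seed)
    smap = MicrostateMap(z_edges=edges, cluster_centers=centers_km)
    bias, ens_ids, slices = compute_bias_energies(trajs, kBT)
    lo, hi = edges[0], edges[-1]
    z_series = [np.where(np.abs(t.z - np.clip(t.z, lo, hi)) <= clip_tol,
                         np.clip(t.z, lo, hi), t.z) for t in trajs]
    segmented, dropped = assign_microstates(z_series, assigns, smap)
    # flatten segments; bias columns keep only in-range frames, in order
    keep_all = np.concatenate([(z >= lo) & (z <= hi) for z in z_series])
    bias = bias[:, keep_all]
    dtrajs, seg_ids, seg_slices = [], [], []
    at = 0
    for eid, segs in zip(ens_ids, segmented):
        for seg in segs:
            dtrajs.append(seg)
            seg_ids.append(eid)
            seg_slices.append(slice(at, at + len(seg)))
            at += len(seg)
    return DiscreteTrajectories(dtrajs=dtrajs, ensemble_ids=seg_ids,
                                bias=bias, traj_slices=seg_slices, map=smap,
                                n_dropped=dropped)
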