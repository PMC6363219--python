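"""Time-lagged independent component analysis (tICA) and feature selection.

tICA finds the linear combinations of input features with maximal
autocorrelation at a fixed lag time; its leading components span the slowest
collective motions and provide the low-dimensional conformational space in
which the Markov-model microstates are clustered.  The estimator here uses
the standard reversible (symmetrized) formulation: time-lagged covariances
are averaged forward/backward so the generalized eigenproblem

    C(tau) v = lambda C(0) v

has real eigenvalues; data from all trajectories (biased and unbiased alike)
are pooled around a common mean.  Eigenvectors are normalized so projections
of the training data have unit variance (v' C0 v = 1, whitened convention)
and oriented so the largest-magnitude loading of each component is positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .simulate import TrajectoryEnsemble

__all__ = [
    "TicaModel",
    "FeatureSelection",
    "estimate_tica",
    "correlate_features_to_tics",
    "select_features_near_density",
]

logger = logging.getLogger(__name__)


@dataclass
class TicaModel:
    """Fitted tICA transform."""

    lag_ns: float
    mean: np.ndarray  # (D,)
    eigenvalues: np.ndarray  # (n_components,), sorted descending
    components: np.ndarray  # (D, n_components) loadings
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project frames (n, D) onto the retained components."""
        return (np.asarray(X, float) - self.mean) @ self.components

    def project_ensemble(self, trajs: TrajectoryEnsemble) -> list[np.ndarray]:
        return [self.transform(t.features) for t in trajs]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# memmpath tica model v1\n")
            fh.write(f"lag_ns\t{float(self.lag_ns)!r}\n")
            fh.write("eigenvalues\t" + "\t".join(repr(float(x)) for x in self.eigenvalues) + "\n")
            fh.write("mean\t" + "\t".join(repr(float(x)) for x in self.mean) + "\n")
            for m in range(self.n_components):
                fh.write(f"component_{m}\t"
                         + "\t".join(repr(float(x)) for x in self.components[:, m]) + "\n")

    @classmethod
    def load(cls, path: str) -> "TicaModel":
        rows = {}
        comps = {}
        with open(path) as fh:
            header = fh.readline()
            if "tica model v1" not in header:
                raise ValueError(f"{path} is not a tica model file")
            for line in fh:
                key, *vals = line.rstrip("\n").split("\t")
                if key.startswith("component_"):
                    comps[int(key.split("_")[1])] = np.array([float(v) for v in vals])
                else:
                    rows[key] = vals
        components = np.column_stack([comps[m] for m in sorted(comps)])
        return cls(
            lag_ns=float(rows["lag_ns"][0]),
            mean=np.array([float(v) for v in rows["mean"]]),
            eigenvalues=np.array([float(v) for v in rows["eigenvalues"]]),
            components=components,
            n_components=components.shape[1],
        )


@dataclass
class FeatureSelection:
    """Per-feature correlation with the retained tICs and the selected set."""

    abs_r: np.ndarray  # (D, n_components)
    selected: np.ndarray  # feature ids with max |r| > threshold
    threshold: float

    def entity_pair_counts(self, pairs: list[tuple[int, int]]) -> dict[int, int]:
        """Rank entities by the number of selected pairs they take part in.

        ``pairs`` maps each feature id to the pair of entities (e.g. residues)
        whose distance it monitors; the report mirrors per-residue pair counts.
        """
        counts: dict[int, int] = {}
        sel = set(int(i) for i in self.selected)
        for fid, (a, b) in enumerate(pairs):
            if fid in sel:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: -kv[1]))

    def to_table(self, path: str) -> None:
        with open(path, "w") as fh:
            ncomp = self.abs_r.shape[1]
            fh.write("feature_id\t" + "\t".join(f"abs_r_tic{m}" for m in range(ncomp))
                     + "\tselected\n")
            sel = set(int(i) for i in self.selected)
            for fid in range(self.abs_r.shape[0]):
                fh.write(f"{fid}\t"
                         + "\t".join(f"{self.abs_r[fid, m]:.6f}" for m in range(ncomp))
                         + f"\t{int(fid in sel)}\n")


def _pooled_frames(trajs: TrajectoryEnsemble) -> list[np.ndarray]:
    out = []
    for t in trajs:
        if t.features is None:
            raise ValueError("trajectories carry no features; run emit_features first")
        if not np.all(np.isfinite(t.features)):
            raise ValueError("non-finite feature values")
        out.append(np.asarray(t.features, float))
    return out


def estimate_tica(
    trajs: TrajectoryEnsemble,
    lag_ns: float = 0.1,
    n_components: int = 2,
    ridge: float = 1e-10,
) -> TicaModel:
    """Fit tICA on the pooled trajectories at the given lag time.

    The lag is converted to frames per trajectory from its own timestep;
    trajectories shorter than the lag are skipped with a warning.  A ridge
    ``ridge`` is added to the instantaneous covariance diagonal to
    regularize degenerate (e.g. duplicated or constant) features.
    """
    frames = _pooled_frames(trajs)
    D = frames[0].shape[1]
    mean = (np.sum([f.sum(axis=0) for f in frames], axis=0)
            / sum(len(f) for f in frames))
    c0 = np.zeros((D, D))
    ct = np.zeros((D, D))
    n_pairs = 0
    n_inst = 0
    for t, f in zip(trajs, frames):
        lag = int(round(lag_ns / t.dt))
        if lag < 1 or lag >= len(f):
            warnings.warn(
                f"trajectory of {len(f)} frames shorter than lag; skipped")
            continue
        x = f - mean
        a, b = x[:-lag], x[lag:]
        c0 += a.T @ a + b.T @ b
        ct += a.T @ b + b.T @ a
        n_pairs += 2 * len(a)
        n_inst += 2 * len(a)
    if n_pairs == 0:
        raise ValueError("no trajectory long enough for the requested lag")
    c0 /= n_inst
    ct /= n_pairs
    c0reg = c0 + ridge * np.eye(D)
    evals, evecs = scipy.linalg.eigh(ct, c0reg)
    order = np.argsort(evals)[::-1][:n_components]
    evals = evals[order]
    evecs = evecs[:, order]
    # eigh(b=...) returns v' C0 v = 1 already; fix sign convention
    for m in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, m]))
        if evecs[j, m] < 0:
            evecs[:, m] *= -1
    return TicaModel(lag_ns=lag_ns, mean=mean, eigenvalues=evals,
                     components=evecs, n_components=len(evals))


def correlate_features_to_tics(
    trajs: TrajectoryEnsemble,
    tica: TicaModel,
    threshold: float = 0.6,
) -> FeatureSelection:
    """Pearson |r| of every feature against every retained tIC, pooled frames.

    Features whose maximum |r| over the retained components exceeds
    ``threshold`` are selected.  Zero-variance features get |r| = 0 and a log
    entry.  Frames from all ensembles (biased and unbiased) are pooled,
    consistent with how the tICA landscape itself is constructed.
    """
    X = np.concatenate(_pooled_frames(trajs), axis=0)
    Y = tica.transform(X)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = Yc.std(axis=0)
    dead = sx == 0
    if dead.any():
        logger.info("%d zero-variance features; |r| set to 0", int(dead.sum()))
    sx_safe = np.where(dead, 1.0, sx)
    r = (Xc.T @ Yc) / len(X) / sx_safe[:, None] / sy[None, :]
    r[dead, :] = 0.0
    abs_r = np.abs(r)
    selected = np.flatnonzero(abs_r.max(axis=1) > threshold)
    return FeatureSelection(abs_r=abs_r, selected=selected, threshold=threshold)


def select_features_near_density(
    grid,
    sensor_positions: np.ndarray,
    cutoff: float = 4.4,
    factor: float = 7.0,
) -> np.ndarray:
    """Feature ids whose sensor lies within ``cutoff`` of a high-density voxel.

    ``grid`` is a :class:`~memmpath.density.DensityGrid` normalized to bulk;
    voxels with normalized density >= ``factor`` count as hotspots.  Sensor
    positions may be scalars (z only) or d-vectors matching the grid
    dimensionality.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if grid.values.size == 0:
        raise ValueError("empty grid")
    hot = np.argwhere(grid.normalized >= factor)
    sensors = np.atleast_2d(np.asarray(sensor_positions, float))
    if sensors.shape[0] == 1 and sensors.shape[1] != grid.ndim:
        sensors = sensors.T
    if hot.size == 0:
        return np.array([], dtype=int)
    hot_pos = grid.origin + (hot + 0.5) * grid.spacing
    d2 = ((sensors[:, None, :] - hot_pos[None, :, :]) ** 2).sum(axis=2)
    return np.flatnonzero((d2 <= cutoff**2).any(axis=1))
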