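"""Parallel-path discovery: DTW distances between reactive trajectories,
k-means grouping, and part-aligned assignment of arbitrary trajectories to
reconstructed reaction coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .dtw import dtw_distance, subsequence_dtw
from .io import FeatureTrajectory
from .regions import ReactiveEnsemble
from .string_method import ReactionCoordinate

__all__ = [
    "DistanceMatrix",
    "PathAssignment",
    "dtw_distance_matrix",
    "cluster_paths",
    "align_to_rcs",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise dissimilarities with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dtw_distance_matrix(reactive) -> DistanceMatrix:
    """Pairwise DTW distances over a reactive ensemble (or trajectory list).

    Trajectories shorter than 2 frames are excluded with a warning; DTW is
    classic, unconstrained, with multivariate Euclidean local cost.
    """
    trajs = list(reactive.trajectories if hasattr(reactive, "trajectories") else reactive)
    usable = [tr for tr in trajs if tr.n_frames >= 2]
    if len(usable) < len(trajs):
        warnings.warn(
            f"excluded {len(trajs) - len(usable)} trajectories shorter than 2 frames",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need at least 2 usable trajectories")
    n = len(usable)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(usable[i].X, usable[j].X)
    return DistanceMatrix(D)


def _half_change_time(x: np.ndarray) -> float:
    """Fraction of the recording at which a coordinate has covered half of
    its net change."""
    lo, hi = x[0], x[-1]
    if hi == lo:
        return 1.0
    prog = (x - lo) / (hi - lo)
    idx = np.argmax(prog >= 0.5) if np.any(prog >= 0.5) else len(x) - 1
    return idx / max(len(x) - 1, 1)


def _texture_lead(tr: FeatureTrajectory, texture_axis: int, morph_axis: int) -> float:
    """How much earlier the texture axis moves than the morphology axis
    (negative = texture-first)."""
    return _half_change_time(tr.X[:, texture_axis]) - _half_change_time(
        tr.X[:, morph_axis]
    )


def cluster_paths(
    D: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    reactive: ReactiveEnsemble | None = None,
    texture_axis: int = 1,
    morph_axis: int = 0,
    method: str = "kmeans",
) -> np.ndarray:
    """Cluster trajectories into path groups from their DTW distance matrix.

    Each trajectory's feature vector is its row of the distance matrix
    (k-means, seeded, 10 restarts); ``method='kmedoids'`` uses a seeded
    alternating k-medoids on the distances instead.  With ``reactive`` given
    and k=2, labels are canonicalized so group 1 is the group whose members
    move the texture axis earlier ("texture-first" convention); groups are
    labeled 1..k.
    """
    if k > D.n:
        raise ValueError(f"k={k} exceeds number of trajectories {D.n}")
    if np.allclose(D.values, D.values.flat[1] if D.n > 1 else 0):
        logger.warning("degenerate all-equal distance matrix; labels arbitrary")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(D.values)
        # rows-as-features k-means can isolate a couple of outlier
        # trajectories into their own cluster; fall back to k-medoids on the
        # distances when the split is that degenerate
        smallest = np.bincount(labels, minlength=k).min()
        if smallest < max(2, 0.05 * D.n):
            logger.warning(
                "k-means produced a degenerate split (smallest group %d); "
                "falling back to k-medoids",
                smallest,
            )
            labels = _kmedoids(D.values, k, seed)
    elif method == "kmedoids":
        labels = _kmedoids(D.values, k, seed)
    else:
        raise ValueError(f"unknown method: {method!r}")
    labels = labels + 1

    if reactive is not None and k == 2 and len(reactive) == D.n:
        leads = np.array(
            [_texture_lead(tr, texture_axis, morph_axis) for tr in reactive]
        )
        mean1 = leads[labels == 1].mean() if (labels == 1).any() else np.inf
        mean2 = leads[labels == 2].mean() if (labels == 2).any() else np.inf
        if mean2 < mean1:  # group 1 = texture moves first
            labels = 3 - labels
    return labels


def _kmedoids(D: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    rng = np.random.default_rng(seed)
    medoids = rng.choice(D.shape[0], size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = np.array(
            [
                np.flatnonzero(labels == c)[
                    np.argmin(D[np.ix_(labels == c, labels == c)].sum(axis=1))
                ]
                if (labels == c).any()
                else medoids[c]
                for c in range(k)
            ]
        )
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


@dataclass
class PathAssignment:
    """Per-frame RC membership of one trajectory.

    ``rc_label[t]`` is 1 or 2; ``matched_s[t]`` the matched arc coordinate;
    ``runs`` the maximal consecutive frame ranges per RC as
    ``(label, start, stop)`` with stop exclusive.
    """

    rc_label: np.ndarray
    matched_s: np.ndarray
    runs: list[tuple[int, int, int]]

    def runs_for(self, label: int) -> list[tuple[int, int]]:
        return [(a, b) for lab, a, b in self.runs if lab == label]


def align_to_rcs(
    traj: FeatureTrajectory,
    rc1: ReactionCoordinate,
    rc2: ReactionCoordinate,
) -> PathAssignment:
    """Part-align one trajectory to two RCs.

    Subsequence DTW (the RC image chain as the query, free to match any
    contiguous window of the trajectory) yields matched arc coordinates for
    frames inside each window; every frame is then assigned to the RC whose
    nearest image is closer in Euclidean distance (ties to RC 1), and maximal
    consecutive runs per RC are reported for per-path drift estimation.
    """
    T = traj.n_frames
    matched = {}
    for label, rc in ((1, rc1), (2, rc2)):
        s_hit = np.full(T, np.nan)
        if T >= 2:
            _, _, path = subsequence_dtw(rc.images, traj.X)
            sums = np.zeros(T)
            cnts = np.zeros(T)
            for qi, sj in path:
                sums[sj] += rc.s[qi]
                cnts[sj] += 1
            hit = cnts > 0
            s_hit[hit] = sums[hit] / cnts[hit]
        matched[label] = s_hit

    d1 = np.min(
        np.linalg.norm(traj.X[:, None, :] - rc1.images[None], axis=2), axis=1
    )
    d2 = np.min(
        np.linalg.norm(traj.X[:, None, :] - rc2.images[None], axis=2), axis=1
    )
    labels = np.where(d2 < d1, 2, 1)  # ties go to RC 1

    matched_s = np.empty(T)
    for t in range(T):
        rc = rc1 if labels[t] == 1 else rc2
        s_hit = matched[labels[t]][t]
        if np.isnan(s_hit):
            s_hit = rc.matched_s(traj.X[t : t + 1])[0]
        matched_s[t] = s_hit

    runs = []
    start = 0
    for t in range(1, T + 1):
        if t == T or labels[t] != labels[start]:
            runs.append((int(labels[start]), start, t))
            start = t
    return PathAssignment(labels, matched_s, runs)
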