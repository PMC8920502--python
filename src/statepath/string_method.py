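"""Reaction-coordinate reconstruction with a revised finite-temperature
string method driven by measured trajectory ensembles.

The RC is a chain of N image points uniformly spaced in arc length whose
Voronoi cells partition the feature space.  Each iteration replaces every
interior image by a weighted average of (i) the mean of the data points in
its Voronoi cell and (ii) the mean over trajectories of each trajectory's
single closest point to that image,

    Xbar(s_k) = (cell_mean_k + w * closest_point_mean_k) / (1 + w),

then refits a smoothing cubic spline through the averages (total squared
residual capped by the smooth factor), resamples N images uniformly in arc
length, and restores the fixed anchors (the E- and M-region data means).
Iteration stops when the data-to-cell Voronoi assignment stops changing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate

from .io import PCAModel, TrajectoryEnsemble
from .regions import ReactiveEnsemble, RegionSpec

__all__ = [
    "ReactionCoordinate",
    "StringMethod",
    "StringResults",
    "voronoi_assign",
    "initialize_string",
    "update_string",
    "converge_string",
    "extrapolate_string",
    "lift_full_dimension",
    "feature_dynamics_along_rc",
]

logger = logging.getLogger(__name__)

MIN_IMAGES = 4


@dataclass
class ReactionCoordinate:
    """An ordered chain of image points with uniform arc spacing.

    ``s`` holds the arc-length position of every image (s[0] = 0); ``anchors``
    are the fixed E/M endpoint means of the *core* string (exclusive of any
    extrapolated images); ``n_extra`` counts extrapolated images per end.
    """

    images: np.ndarray
    s: np.ndarray
    anchors: np.ndarray
    n_extra: int = 0

    def __post_init__(self) -> None:
        self.images = np.atleast_2d(np.asarray(self.images, float))
        self.s = np.asarray(self.s, float)
        if self.images.shape[0] != self.s.shape[0]:
            raise ValueError("images and s must have equal length")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def d(self) -> int:
        return self.images.shape[1]

    @property
    def ds(self) -> float:
        return float(np.mean(np.diff(self.s)))

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Voronoi assignment: nearest image index, ties to the lower index."""
        return voronoi_assign(points, self.images)

    def matched_s(self, points: np.ndarray) -> np.ndarray:
        """Arc coordinate of the Voronoi cell containing each point."""
        return self.s[self.assign(points)]

    def interior_slice(self) -> slice:
        """Cells used for drift/diffusion: all but the first and last."""
        return slice(1, self.n_images - 1)


def voronoi_assign(points: np.ndarray, images: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, float))
    d2 = np.sum((points[:, None, :] - images[None, :, :]) ** 2, axis=2)
    return np.argmin(d2, axis=1)  # argmin takes the first (lowest) index


def _region_means(
    ensemble: TrajectoryEnsemble, regions: RegionSpec
) -> tuple[np.ndarray, np.ndarray]:
    X = ensemble.stacked()
    in_E = np.linalg.norm(X - regions.E_center, axis=1) <= regions.E_radius
    in_M = np.linalg.norm(X - regions.M_center, axis=1) <= regions.M_radius
    if not in_E.any() or not in_M.any():
        raise ValueError("both E and M regions must contain data points")
    return X[in_E].mean(axis=0), X[in_M].mean(axis=0)


def initialize_string(
    ensemble: ReactiveEnsemble | TrajectoryEnsemble,
    regions: RegionSpec,
    n_images: int = 30,
) -> ReactionCoordinate:
    """Straight-line initial string between the E- and M-region data means."""
    if n_images < MIN_IMAGES:
        raise ValueError(f"need at least {MIN_IMAGES} images, got {n_images}")
    ens = ensemble.ensemble if isinstance(ensemble, ReactiveEnsemble) else ensemble
    e_mean, m_mean = _region_means(ens, regions)
    frac = np.linspace(0.0, 1.0, n_images)[:, None]
    images = e_mean + frac * (m_mean - e_mean)
    length = float(np.linalg.norm(m_mean - e_mean))
    s = np.linspace(0.0, length, n_images)
    return ReactionCoordinate(images, s, anchors=np.stack([e_mean, m_mean]))


def _resample_uniform(points: np.ndarray, n: int, smooth: float) -> np.ndarray:
    """Smoothing cubic spline through ``points``, resampled uniformly in arc
    length.  Endpoints get a large spline weight so they are interpolated."""
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )
    if chord[-1] == 0:
        return np.tile(points[0], (n, 1))
    u = chord / chord[-1]
    wts = np.ones(len(points))
    wts[[0, -1]] = 1e4
    k = min(3, len(points) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fitpack chatter on tight budgets
        tck, _ = interpolate.splprep(points.T, u=u, w=wts, s=smooth, k=k)
    dense_u = np.linspace(0.0, 1.0, 1000)
    dense = np.stack(interpolate.splev(dense_u, tck), axis=1)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, points.shape[1]))
    for j in range(points.shape[1]):
        out[:, j] = np.interp(targets, arc, dense[:, j])
    return out


def update_string(
    rc: ReactionCoordinate,
    ensemble: ReactiveEnsemble | TrajectoryEnsemble,
    w: float = 10.0,
    smooth: float = 1.0,
    closest_per: str = "trajectory",
) -> ReactionCoordinate:
    """One string iteration: weighted-average step, spline, reparameterize.

    ``closest_per='trajectory'`` averages one closest point per trajectory in
    the second term; ``'visit'`` averages one per visit to the cell instead.
    """
    ens = ensemble.ensemble if isinstance(ensemble, ReactiveEnsemble) else ensemble
    X = ens.stacked()
    assign = rc.assign(X)
    K = rc.n_images

    term2 = np.empty_like(rc.images)
    if closest_per == "trajectory":
        closest = []
        for tr in ens:
            d2 = np.sum((tr.X[:, None, :] - rc.images[None, :, :]) ** 2, axis=2)
            closest.append(tr.X[np.argmin(d2, axis=0)])  # (K, d) per trajectory
        term2[:] = np.mean(closest, axis=0)
    elif closest_per == "visit":
        term2[:] = np.array(
            [X[assign == k].mean(axis=0) if (assign == k).any() else rc.images[k]
             for k in range(K)]
        )
    else:
        raise ValueError(f"unknown closest_per: {closest_per!r}")

    xbar = np.empty_like(rc.images)
    empty = 0
    for k in range(K):
        members = X[assign == k]
        if len(members):
            xbar[k] = (members.mean(axis=0) + w * term2[k]) / (1.0 + w)
        else:
            xbar[k] = term2[k]
            empty += 1
    if empty == K:
        raise RuntimeError("all Voronoi cells are empty; string cannot update")
    if empty:
        logger.debug("%d empty Voronoi cells fell back to the trajectory term", empty)

    xbar[0], xbar[-1] = rc.anchors[0], rc.anchors[1]
    images = _resample_uniform(xbar, K, smooth)
    images[0], images[-1] = rc.anchors[0], rc.anchors[1]
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(images, axis=0), axis=1))]
    )
    return ReactionCoordinate(images, arc, anchors=rc.anchors.copy())


def converge_string(
    rc0: ReactionCoordinate,
    ensemble: ReactiveEnsemble | TrajectoryEnsemble,
    w: float = 10.0,
    smooth: float = 1.0,
    max_iter: int = 100,
    closest_per: str = "trajectory",
):
    """Iterate assign/update until the Voronoi assignment is stationary.

    Returns ``(rc, n_iter, converged)``.  Oscillating assignments (cycle
    period <= 4) terminate the loop with ``converged=False``.
    """
    ens = ensemble.ensemble if isinstance(ensemble, ReactiveEnsemble) else ensemble
    X = ens.stacked()
    rc = rc0
    prev = rc.assign(X)
    recent: list[bytes] = [prev.tobytes()]
    for it in range(1, max_iter + 1):
        rc = update_string(rc, ensemble, w=w, smooth=smooth, closest_per=closest_per)
        cur = rc.assign(X)
        key = cur.tobytes()
        if key == recent[-1]:
            return rc, it, True
        if key in recent[:-1]:
            logger.warning("string iteration entered a cycle; returning last iterate")
            return rc, it, False
        recent.append(key)
        recent = recent[-5:]
    logger.warning("string did not converge within %d iterations", max_iter)
    return rc, max_iter, False


def extrapolate_string(rc: ReactionCoordinate, n_extra: int = 3) -> ReactionCoordinate:
    """Extend the string linearly by ``n_extra`` images beyond each end,
    keeping the interior arc spacing."""
    if n_extra == 0:
        return rc
    ds = rc.ds
    head_dir = rc.images[0] - rc.images[1]
    tail_dir = rc.images[-1] - rc.images[-2]
    head_dir = head_dir / np.linalg.norm(head_dir)
    tail_dir = tail_dir / np.linalg.norm(tail_dir)
    head = [rc.images[0] + ds * (i + 1) * head_dir for i in range(n_extra)]
    tail = [rc.images[-1] + ds * (i + 1) * tail_dir for i in range(n_extra)]
    images = np.vstack([head[::-1], rc.images, tail])
    s = np.arange(images.shape[0]) * ds
    return ReactionCoordinate(images, s, anchors=rc.anchors.copy(), n_extra=n_extra)


def lift_full_dimension(
    rc: ReactionCoordinate, full_ensemble: TrajectoryEnsemble
) -> ReactionCoordinate:
    """Extend RC images into extra feature dimensions by per-cell data means.

    The full ensemble's leading ``rc.d`` coordinates must be the RC's
    subspace; the remaining coordinates of each image are set to the mean of
    its Voronoi cell members there, empty cells interpolated from neighbors.
    """
    d_full = full_ensemble.d
    if d_full < rc.d:
        raise ValueError(f"full ensemble has {d_full} < {rc.d} coordinates")
    X_full = full_ensemble.stacked()
    assign = rc.assign(X_full[:, : rc.d])
    K = rc.n_images
    extra = np.full((K, d_full - rc.d), np.nan)
    for k in range(K):
        members = X_full[assign == k][:, rc.d :]
        if len(members):
            extra[k] = members.mean(axis=0)
    for j in range(extra.shape[1]):
        col = extra[:, j]
        holes = np.isnan(col)
        if holes.any():
            logger.debug("interpolating %d empty cells in lifted dim %d",
                         holes.sum(), rc.d + j)
            col[holes] = np.interp(
                np.flatnonzero(holes), np.flatnonzero(~holes), col[~holes]
            )
    images = np.hstack([rc.images, extra])
    anchors = np.hstack([rc.anchors, images[[0, -1]][:, rc.d :]])
    return ReactionCoordinate(images, rc.s.copy(), anchors, rc.n_extra)


def feature_dynamics_along_rc(
    lifted_rc: ReactionCoordinate, pca: PCAModel
) -> np.ndarray:
    """Original-space feature curves along the RC, (n_images, D).

    Inverse-transforms the lifted image coordinates through the PCA model;
    column ``f`` is the trajectory of original feature ``f`` versus arc
    length.
    """
    if lifted_rc.d != pca.d:
        raise ValueError(
            f"RC dimension {lifted_rc.d} does not match PCA subspace {pca.d}"
        )
    return pca.inverse_transform(lifted_rc.images)


# ---------------------------------------------------------------------------
# model facade


class StringMethod:
    """Finite-temperature-string estimator of a reaction coordinate.

    Parameters
    ----------
    ensemble : the (reactive) trajectory ensemble driving the string.
    regions : E/M ball geometry supplying the fixed anchors.
    n_images : number of images N discretizing the string (default 30).
    w : weight of the per-trajectory closest-point term (default 10).
    smooth : smoothing-spline residual budget per iteration (default 1).
    """

    def __init__(
        self,
        ensemble: ReactiveEnsemble | TrajectoryEnsemble,
        regions: RegionSpec,
        n_images: int = 30,
        w: float = 10.0,
        smooth: float = 1.0,
        closest_per: str = "trajectory",
    ):
        self.ensemble = ensemble
        self.regions = regions
        self.n_images = n_images
        self.w = w
        self.smooth = smooth
        self.closest_per = closest_per

    def fit(self, max_iter: int = 100) -> "StringResults":
        rc0 = initialize_string(self.ensemble, self.regions, self.n_images)
        if max_iter == 0:
            return StringResults(self, rc0, 0, False)
        rc, n_iter, converged = converge_string(
            rc0,
            self.ensemble,
            w=self.w,
            smooth=self.smooth,
            max_iter=max_iter,
            closest_per=self.closest_per,
        )
        return StringResults(self, rc, n_iter, converged)


class StringResults:
    """A fitted reaction coordinate plus convergence diagnostics."""

    def __init__(self, model, rc, n_iter, converged):
        self.model = model
        self.rc = rc
        self.n_iter = n_iter
        self.converged = converged

    def extrapolate(self, n_extra: int = 3) -> ReactionCoordinate:
        return extrapolate_string(self.rc, n_extra)

    def lift(self, full_ensemble: TrajectoryEnsemble) -> ReactionCoordinate:
        return lift_full_dimension(self.rc, full_ensemble)

    def summary(self) -> str:
        rc = self.rc
        lines = [
            "String method results",
            f"  images:       {rc.n_images} (dimension {rc.d})",
            f"  arc length:   {rc.s[-1]:.4g}",
            f"  arc spacing:  {rc.ds:.4g}",
            f"  iterations:   {self.n_iter}",
            f"  converged:    {self.converged}",
        ]
        return "\n".join(lines)
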