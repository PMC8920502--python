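"""E/I/M region geometry, reactive-trajectory extraction, and density maps.

The feature space is split into an epithelial region E and a mesenchymal
region M (closed balls around empirical centers) with everything else the
intermediate region I.  A reactive trajectory is one recorded pass that
starts inside E and reaches M by a deadline — the practical single-recording
reading of transition-path theory, not the infinite-trajectory segment
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter

from .io import FeatureTrajectory, TrajectoryEnsemble

__all__ = [
    "RegionSpec",
    "ReactiveEnsemble",
    "DensityMap",
    "assign_region",
    "label_trajectory",
    "extract_reactive",
    "kernel_density",
    "reactive_density_map",
    "ridge_modes",
]


@dataclass(frozen=True)
class RegionSpec:
    """Closed-ball E and M regions; I is the complement of their union."""

    E_center: np.ndarray
    M_center: np.ndarray
    E_radius: float
    M_radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "E_center", np.asarray(self.E_center, float))
        object.__setattr__(self, "M_center", np.asarray(self.M_center, float))
        if self.E_radius <= 0 or self.M_radius <= 0:
            raise ValueError("region radii must be positive")
        gap = np.linalg.norm(self.M_center - self.E_center)
        if gap <= self.E_radius + self.M_radius:
            raise ValueError("E and M balls must be disjoint")

    @property
    def d(self) -> int:
        return self.E_center.shape[0]


def assign_region(x: np.ndarray, regions: RegionSpec) -> str:
    """Label a single point E, I, or M (boundary points belong to the ball)."""
    x = np.asarray(x, float)
    if x.shape != (regions.d,):
        raise ValueError(f"point has shape {x.shape}, expected ({regions.d},)")
    if np.linalg.norm(x - regions.E_center) <= regions.E_radius:
        return "E"
    if np.linalg.norm(x - regions.M_center) <= regions.M_radius:
        return "M"
    return "I"


def label_trajectory(traj: FeatureTrajectory, regions: RegionSpec) -> np.ndarray:
    """Vectorized per-frame labels, array of 'E'/'I'/'M'."""
    dE = np.linalg.norm(traj.X - regions.E_center, axis=1)
    dM = np.linalg.norm(traj.X - regions.M_center, axis=1)
    labels = np.full(traj.n_frames, "I", dtype="<U1")
    labels[dE <= regions.E_radius] = "E"
    labels[dM <= regions.M_radius] = "M"
    return labels


@dataclass
class ReactiveEnsemble:
    """The reactive subset of an ensemble with entry bookkeeping.

    ``first_M_entry[i]`` is the frame index at which trajectory ``i`` first
    enters M; members start in E by construction.
    """

    ensemble: TrajectoryEnsemble
    regions: RegionSpec
    first_M_entry: list[int] = field(default_factory=list)

    @property
    def trajectories(self):
        return self.ensemble.trajectories

    def __len__(self) -> int:
        return len(self.ensemble)

    def __iter__(self):
        return iter(self.ensemble)

    def transition_segments(self, pad: int = 5) -> TrajectoryEnsemble:
        """The transition passes: each member truncated shortly after its
        first M entry (``pad`` extra frames).  This is the natural input for
        state-space discretization of the transition itself — long dwell in
        the product basin would otherwise dominate the state allocation."""
        trs = []
        for tr, entry in zip(self.ensemble, self.first_M_entry):
            stop = min(tr.n_frames, entry + 1 + pad)
            trs.append(FeatureTrajectory(tr.cell_id, tr.times[:stop], tr.X[:stop]))
        return TrajectoryEnsemble(
            trs,
            list(self.ensemble.feature_names),
            self.ensemble.dt,
            self.ensemble.condition_label,
        )


def extract_reactive(
    ensemble: TrajectoryEnsemble, regions: RegionSpec, deadline: float = 48.0
) -> ReactiveEnsemble:
    """Keep trajectories that start in E and reach M at or before ``deadline``.

    The deadline is in the ensemble's time units (hours); an empty result is
    allowed and returns a ReactiveEnsemble whose inner list is empty (the
    TrajectoryEnsemble non-empty invariant is bypassed via the subset of kept
    indices, so callers must check ``len``).
    """
    kept, entries = [], []
    for tr in ensemble:
        labels = label_trajectory(tr, regions)
        if labels[0] != "E":
            continue
        hits = np.where((labels == "M") & (tr.times <= deadline))[0]
        if hits.size == 0:
            continue
        kept.append(tr)
        entries.append(int(hits[0]))
    if not kept:
        sub = TrajectoryEnsemble.__new__(TrajectoryEnsemble)
        sub.trajectories = []
        sub.feature_names = list(ensemble.feature_names)
        sub.dt = ensemble.dt
        sub.condition_label = ensemble.condition_label
    else:
        sub = TrajectoryEnsemble(
            kept, list(ensemble.feature_names), ensemble.dt, ensemble.condition_label
        )
    return ReactiveEnsemble(sub, regions, entries)


def kernel_density(
    points: np.ndarray, eval_grid: np.ndarray, bandwidth: float | str = "scott"
) -> np.ndarray:
    """Gaussian kernel density estimate evaluated on a grid of points.

    ``points`` is (n, d); ``eval_grid`` is (m, d).  Delegates to
    ``scipy.stats.gaussian_kde``; bandwidth is a scalar factor or a rule name.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] < 2:
        raise ValueError("kernel density needs at least 2 points")
    if isinstance(bandwidth, (int, float)) and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(points.T, bw_method=bandwidth)
    return kde(np.atleast_2d(eval_grid).T)


@dataclass
class DensityMap:
    """Reactive-trajectory density on a 2-D plane of two feature axes.

    ``values[i, j]`` is the (smoothed) count for bin i of the first axis and
    bin j of the second; bins are half-open [lo, hi) except the last, closed.
    """

    axes: tuple[int, int]
    bounds: tuple[tuple[float, float], tuple[float, float]]
    values: np.ndarray
    raw_counts: np.ndarray
    sigma: float
    truncate: float

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_centers(self, axis: int) -> np.ndarray:
        lo, hi = self.bounds[axis]
        edges = np.linspace(lo, hi, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def local_maxima(self, min_rel_height: float = 0.2) -> list[tuple[int, int]]:
        """Grid cells that strictly dominate their 8-neighborhood and exceed
        ``min_rel_height`` of the global maximum — the ridge peaks."""
        v = self.values
        peak = v.max()
        out = []
        for i in range(1, v.shape[0] - 1):
            for j in range(1, v.shape[1] - 1):
                c = v[i, j]
                if c < min_rel_height * peak:
                    continue
                patch = v[i - 1 : i + 2, j - 1 : j + 2]
                if c >= patch.max() and np.sum(patch == c) == 1:
                    out.append((i, j))
        return out


def ridge_modes(
    dmap: DensityMap,
    E_center: np.ndarray,
    M_center: np.ndarray,
    band: tuple[float, float] = (0.3, 0.7),
    min_rel_height: float = 0.25,
    merge_dist: float = 3.0,
    n_transverse_bins: int = 60,
    profile_sigma: float = 1.5,
) -> list[tuple[float, float]]:
    """Distinct transition corridors of a reactive density map.

    The map's mass within the middle ``band`` of the E->M axis is projected
    onto the transverse direction; modes of that 1-D profile above
    ``min_rel_height`` of its peak, merged when closer than ``merge_dist``
    (map units), are the parallel transition channels.  Returns
    ``(transverse position, profile height)`` per mode, sorted by position;
    ``len`` of the result is the ridge count.
    """
    from scipy.ndimage import gaussian_filter1d

    E_center = np.asarray(E_center, float)[list(dmap.axes)]
    M_center = np.asarray(M_center, float)[list(dmap.axes)]
    x = dmap.bin_centers(0)
    y = dmap.bin_centers(1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    vals = dmap.values.ravel()
    u = M_center - E_center
    L = np.linalg.norm(u)
    u = u / L
    vperp = np.array([-u[1], u[0]])
    t = (pts - E_center) @ u
    w = (pts - E_center) @ vperp
    sel = (t > band[0] * L) & (t < band[1] * L)
    prof, edges = np.histogram(w[sel], bins=n_transverse_bins, weights=vals[sel])
    prof = gaussian_filter1d(prof, profile_sigma)
    peak = prof.max()
    if peak <= 0:
        return []
    modes = []
    for i in range(1, n_transverse_bins - 1):
        if prof[i] >= min_rel_height * peak and prof[i] > prof[i - 1] and prof[i] >= prof[i + 1]:
            modes.append((0.5 * (edges[i] + edges[i + 1]), float(prof[i])))
    merged: list[tuple[float, float]] = []
    for pos, h in modes:
        if merged and abs(pos - merged[-1][0]) < merge_dist:
            if h > merged[-1][1]:
                merged[-1] = (pos, h)
            continue
        merged.append((pos, h))
    return merged


def _bin_index(x: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(int)
    idx[x == hi] = n_bins - 1  # last bin closed
    return idx


def reactive_density_map(
    reactive: ReactiveEnsemble,
    axes: tuple[int, int] = (0, 1),
    n_bins: int = 200,
    sigma: float = 2.0,
    truncate: float = 2.0,
    bounds=None,
) -> DensityMap:
    """Occupancy map of reactive trajectories in a 2-feature plane.

    Only intermediate-region frames of the transition pass (start through
    first M entry) contribute; a trajectory adds at most 1 to any grid cell
    however many times it revisits it.  The raw count matrix is then smoothed
    with a Gaussian filter of ``sigma`` grid cells truncated at ``truncate``
    standard deviations.  Bounds default to the data min/max per axis
    expanded by 5%.
    """
    if len(reactive) == 0:
        raise ValueError("reactive ensemble is empty")
    d = reactive.ensemble.d
    if not all(0 <= a < d for a in axes):
        raise ValueError(f"axes {axes} out of range for dimension {d}")

    entries = reactive.first_M_entry or [None] * len(reactive)
    planes = []
    for tr, entry in zip(reactive, entries):
        stop = tr.n_frames if entry is None else entry + 1
        labels = label_trajectory(tr, reactive.regions)[:stop]
        pts = tr.X[:stop][labels == "I"][:, list(axes)]
        planes.append(pts)
    if bounds is None:
        allpts = np.vstack([p for p in planes if len(p)] or [np.zeros((1, 2))])
        bounds = []
        for k in range(2):
            lo, hi = allpts[:, k].min(), allpts[:, k].max()
            pad = 0.05 * (hi - lo) if hi > lo else 1.0
            bounds.append((lo - pad, hi + pad))
        bounds = tuple(bounds)

    counts = np.zeros((n_bins, n_bins))
    for pts in planes:
        if len(pts) == 0:
            continue
        i = _bin_index(pts[:, 0], *bounds[0], n_bins)
        j = _bin_index(pts[:, 1], *bounds[1], n_bins)
        ok = (i >= 0) & (i < n_bins) & (j >= 0) & (j < n_bins)
        cells = np.unique(np.stack([i[ok], j[ok]], axis=1), axis=0)
        counts[cells[:, 0], cells[:, 1]] += 1.0  # binary per trajectory

    smooth = gaussian_filter(counts, sigma=sigma, truncate=truncate, mode="constant")
    return DensityMap(tuple(axes), bounds, smooth, counts, sigma, truncate)
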