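"""Drift, diffusion and quasi-potential estimation along a reaction
coordinate, plus the Chapman-Kolmogorov Markovianity test.

The 1-D ansatz is ds/dt = -dphi/ds + eta.  Within each interior Voronoi cell
i of an (extrapolated) RC the drift estimator is

    dphi/ds |_i = - < ( s(X(t+dt)) - s_i ) / dt >   over frames with X(t) in cell i,

where s(X) is the arc coordinate of the Voronoi cell containing X, and the
diffusion is the sample variance of the same per-cell velocity samples.
Both reactive and non-reactive trajectory segments feed the averages (the
noise has zero mean only under unbiased within-cell sampling).  The
quasi-potential follows by a left-Riemann cumulative sum, and a stationary
sample yields the reference potential phi0 = -log p_ss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrajectoryEnsemble
from .string_method import ReactionCoordinate

__all__ = [
    "QuasiPotentialModel",
    "QuasiPotentialResults",
    "integrate_potential",
    "potential_from_density",
    "CKTestResult",
    "ck_deviation",
    "ck_test",
    "uniform_rc_1d",
]

logger = logging.getLogger(__name__)


def uniform_rc_1d(lo: float, hi: float, n_cells: int, n_extra: int = 1) -> ReactionCoordinate:
    """A straight 1-D reaction coordinate whose interior cells tile [lo, hi].

    ``n_extra`` boundary images per end are added outside the range so the
    first/last (ignored) Voronoi cells absorb out-of-range excursions.
    """
    ds = (hi - lo) / (n_cells - 1)
    images = np.linspace(lo - n_extra * ds, hi + n_extra * ds, n_cells + 2 * n_extra)
    s = np.arange(images.shape[0]) * ds
    anchors = np.array([[lo], [hi]])
    return ReactionCoordinate(images[:, None], s, anchors, n_extra=n_extra)


def _segments_from_ensemble(ensemble: TrajectoryEnsemble):
    return [tr.X for tr in ensemble]


def _velocity_samples(segments, rc: ReactionCoordinate, dt: float):
    """Per-cell lists of (s(X(t+dt)) - s_i)/dt samples over all segments."""
    K = rc.n_images
    samples: list[list[float]] = [[] for _ in range(K)]
    for X in segments:
        if len(X) < 2:
            continue
        cells = rc.assign(X)
        s_next = rc.s[cells[1:]]
        s_here = rc.s[cells[:-1]]
        v = (s_next - s_here) / dt
        for c, vi in zip(cells[:-1], v):
            samples[c].append(vi)
    return samples


class QuasiPotentialModel:
    """Quasi-potential estimator along one reaction coordinate.

    Parameters
    ----------
    ensemble : trajectories feeding the per-cell velocity samples (reactive
        and non-reactive alike).
    rc : an extrapolated ReactionCoordinate (``n_extra`` > 0); its first and
        last Voronoi cells are ignored.
    min_count : minimum samples per cell before the cell's drift/diffusion is
        trusted; sparser cells are masked and interpolated for integration.
    dt : sampling interval for the velocity estimator; defaults to the
        ensemble frame interval.
    segments : optional explicit list of (T, d) consecutive-frame arrays,
        overriding ``ensemble`` — used for part-aligned per-path estimation.
    """

    def __init__(
        self,
        ensemble: TrajectoryEnsemble | None,
        rc: ReactionCoordinate,
        min_count: int = 5,
        dt: float | None = None,
        segments=None,
    ):
        if rc.n_extra == 0:
            raise ValueError("rc must be extrapolated (n_extra > 0) before estimation")
        if ensemble is None and segments is None:
            raise ValueError("either ensemble or segments is required")
        self.ensemble = ensemble
        self.rc = rc
        self.min_count = min_count
        self.dt = dt if dt is not None else ensemble.dt
        self.segments = (
            segments if segments is not None else _segments_from_ensemble(ensemble)
        )

    @classmethod
    def from_path_assignments(
        cls,
        ensemble: TrajectoryEnsemble,
        rc: ReactionCoordinate,
        assignments,
        label: int,
        **kwargs,
    ) -> "QuasiPotentialModel":
        """Build the model from the maximal consecutive runs assigned to one
        RC by part-aligning (see ``clustering.align_to_rcs``)."""
        segs = []
        for tr, pa in zip(ensemble, assignments):
            for a, b in pa.runs_for(label):
                if b - a >= 2:
                    segs.append(tr.X[a:b])
        return cls(None, rc, dt=kwargs.pop("dt", ensemble.dt), segments=segs, **kwargs)

    def fit(self) -> "QuasiPotentialResults":
        rc = self.rc
        samples = _velocity_samples(self.segments, rc, self.dt)
        interior = rc.interior_slice()
        idx = np.arange(rc.n_images)[interior]
        counts = np.array([len(samples[i]) for i in idx])
        grad = np.full(len(idx), np.nan)
        grad_se = np.full(len(idx), np.nan)
        diff = np.full(len(idx), np.nan)
        for row, i in enumerate(idx):
            v = np.asarray(samples[i])
            if len(v) >= self.min_count:
                grad[row] = -np.mean(v)
                diff[row] = np.var(v, ddof=1)
                grad_se[row] = np.std(v, ddof=1) / np.sqrt(len(v))
        if np.all(np.isnan(grad)):
            raise RuntimeError("all interior cells are masked; not enough data")
        return QuasiPotentialResults(
            model=self,
            s_grid=rc.s[interior].copy(),
            grad=grad,
            grad_se=grad_se,
            D=diff,
            counts=counts,
        )


def integrate_potential(grad: np.ndarray, ds: float) -> np.ndarray:
    """Left-Riemann cumulative integral of dphi/ds with phi(s0) = 0.

    Masked (NaN) interior values are filled by linear interpolation first;
    leading/trailing masked cells truncate the domain (the caller sees the
    shorter phi and should align via the mask).
    """
    grad = np.asarray(grad, float)
    mask = np.isnan(grad)
    if mask.all():
        raise ValueError("no unmasked gradient values to integrate")
    if mask.any():
        first, last = np.flatnonzero(~mask)[[0, -1]]
        grad = grad[first : last + 1].copy()
        inner = np.isnan(grad)
        if inner.any():
            logger.info("interpolating %d masked interior cells", inner.sum())
            grad[inner] = np.interp(
                np.flatnonzero(inner), np.flatnonzero(~inner), grad[~inner]
            )
    return np.concatenate([[0.0], ds * np.cumsum(grad)])


def potential_from_density(
    points: np.ndarray, rc: ReactionCoordinate, pseudocount: float = 0.5
) -> np.ndarray:
    """Boltzmann-inverted stationary potential phi0 = -log p_ss per cell.

    ``points`` is a stationary sample (e.g. untreated control cells); counts
    are taken over the interior Voronoi cells, regularized by ``pseudocount``
    and normalized; the result is offset so its minimum is zero.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] == 0:
        raise ValueError("empty stationary sample")
    cells = rc.assign(points)
    interior = np.arange(rc.n_images)[rc.interior_slice()]
    counts = np.array([(cells == i).sum() for i in interior], dtype=float)
    p = (counts + pseudocount) / (counts + pseudocount).sum()
    phi0 = -np.log(p)
    return phi0 - phi0.min()


@dataclass
class QuasiPotentialResults:
    """Per-cell drift gradient, diffusion, and the integrated potential."""

    model: QuasiPotentialModel
    s_grid: np.ndarray
    grad: np.ndarray
    grad_se: np.ndarray
    D: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.ds = float(self.model.rc.ds)
        # raw integral with its phi(s0)=0 reference point prepended
        self.phi = integrate_potential(self.grad, self.ds)
        # phi aligned with s_grid: cell i accumulates grads up to and
        # including cell i; NaN on the masked leading/trailing span
        first = int(np.flatnonzero(~self.mask)[0])
        cells = np.full(len(self.s_grid), np.nan)
        cells[first : first + len(self.phi) - 1] = self.phi[1:]
        self.phi_cells = cells

    @property
    def mask(self) -> np.ndarray:
        """True where the cell had too few samples to be trusted."""
        return np.isnan(self.grad)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": self.s_grid,
                "grad": self.grad,
                "grad_se": self.grad_se,
                "phi": self.phi_cells,
                "D": self.D,
                "counts": self.counts,
            }
        )

    def summary(self) -> str:
        ok = ~self.mask
        lines = [
            "Quasi-potential along reaction coordinate",
            f"  interior cells:     {len(self.s_grid)} (ds = {self.ds:.4g})",
            f"  estimated cells:    {ok.sum()}  (masked: {self.mask.sum()}, "
            f"min_count = {self.model.min_count})",
            f"  samples used:       {int(self.counts.sum())}",
            f"  mean diffusion D:   {np.nanmean(self.D):.4g}",
            f"  potential range:    {np.nanmax(self.phi_cells) - np.nanmin(self.phi_cells):.4g}",
        ]
        return "\n".join(lines)

    def solve_fokker_planck(self, kBT: float = 0.5, grid_n: int = 200, **kwargs):
        """Predict the stationary density from the fitted (phi, D); see
        :func:`statepath.fokker_planck.solve_fokker_planck`."""
        from .fokker_planck import solve_fokker_planck

        ok = ~self.mask
        s = self.s_grid[ok]
        phi = self.phi_cells[ok]
        D = self.D[ok]
        return solve_fokker_planck(s, phi, D, kBT=kBT, grid_n=grid_n, **kwargs)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test


@dataclass
class CKTestResult:
    """Deviation between P(k*tau) and P(tau)^k per k.

    ``deviations[k]`` is the maximum row-wise L1 difference over states with
    enough lagged pairs at both lags; exactly zero at k = 1 by construction.
    """

    tau: int
    ks: tuple[int, ...]
    deviations: dict[int, float]
    per_state: dict[int, np.ndarray] = field(default_factory=dict)

    def max_deviation(self) -> float:
        return max(self.deviations.values())


def _lagged_matrix(sequences, n_states: int, lag: int):
    C = np.zeros((n_states, n_states))
    for seq in sequences:
        if len(seq) > lag:
            np.add.at(C, (seq[:-lag], seq[lag:]), 1.0)
    rows = C.sum(axis=1)
    P = np.divide(C, rows[:, None], out=np.zeros_like(C), where=rows[:, None] > 0)
    return P, rows


def ck_deviation(
    sequences,
    n_states: int | None = None,
    tau: int = 1,
    ks: tuple[int, ...] = (2, 3, 4, 5),
    min_count: int = 10,
) -> CKTestResult:
    """Chapman-Kolmogorov test on integer state sequences.

    Compares the k*tau-lag empirical transition matrix against the k-th power
    of the tau-lag matrix; a Markovian process gives deviations at the
    sampling-noise level for every k.
    """
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    if n_states is None:
        n_states = int(max(s.max() for s in sequences)) + 1
    P1, rows1 = _lagged_matrix(sequences, n_states, tau)
    result = CKTestResult(tau=tau, ks=tuple(ks), deviations={1: 0.0})
    for k in ks:
        Pk, rowsk = _lagged_matrix(sequences, n_states, k * tau)
        power = np.linalg.matrix_power(P1, k)
        valid = (rows1 >= min_count) & (rowsk >= min_count)
        if not valid.any():
            raise ValueError(f"no state has {min_count} lagged pairs at k={k}")
        l1 = np.abs(Pk - power).sum(axis=1)
        l1[~valid] = np.nan
        result.per_state[k] = l1
        result.deviations[k] = float(np.nanmax(l1))
    return result


def ck_test(
    ensemble: TrajectoryEnsemble,
    rc: ReactionCoordinate,
    tau: int = 1,
    ks: tuple[int, ...] = (2, 3, 4, 5),
    min_count: int = 10,
) -> CKTestResult:
    """CK test with the RC's Voronoi cells as the discrete state space."""
    sequences = [rc.assign(tr.X) for tr in ensemble]
    return ck_deviation(sequences, rc.n_images, tau, ks, min_count)
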