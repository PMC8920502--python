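"""Seeded synthetic trajectory generators.

Every downstream stage of the pipeline (reactive extraction, SOM transition
networks, DTW clustering, string method, quasi-potential estimation,
Fokker-Planck prediction) is verified by parameter recovery on ensembles
generated here: overdamped Langevin dynamics

    dx/dt = -grad U(x) + eta(x, t),    <eta> = 0, white Gaussian,

integrated with Euler-Maruyama on analytic landscapes.  The flagship fixture
is a two-dimensional landscape with an epithelial-like well that is
destabilized by a dose-like control parameter, opening two transition
channels toward a mesenchymal-like well: one channel moves the texture-like
axis first, the other moves both axes concertedly.  The two channel barriers
vanish at different control values, emulating sequential saddle-node
collisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import FeatureTrajectory, PCAModel, TrajectoryEnsemble, ValidationError

__all__ = [
    "GaussianTerm",
    "PotentialSpec",
    "SimulationConfig",
    "make_two_path_potential",
    "simulate_langevin",
    "simulate_two_path_ensemble",
    "make_markov_fixture",
    "make_pca_fixture",
    "quadratic_well",
    "quartic_double_well",
    "TWO_PATH_E_CENTER",
    "TWO_PATH_M_CENTER",
    "TWO_PATH_SIM",
    "two_path_regions",
    "channel_centerline",
    "channel_barriers",
]


@dataclass(frozen=True)
class GaussianTerm:
    """One well (height < 0) or barrier (height > 0) of a landscape."""

    center: tuple[float, ...]
    height: float
    width: tuple[float, ...]

    def energy(self, X: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        w = np.asarray(self.width)
        z = (X - c) / w
        return self.height * np.exp(-0.5 * np.sum(z * z, axis=-1))

    def gradient(self, X: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        w = np.asarray(self.width)
        diff = X - c
        e = self.height * np.exp(-0.5 * np.sum((diff / w) ** 2, axis=-1))
        return -e[..., None] * diff / w**2


@dataclass
class PotentialSpec:
    """Analytic landscape: Gaussian wells/barriers plus optional confinement.

    ``bowl_kappa * |x - bowl_center|^2`` keeps the landscape finite-minimum;
    ``tilt . x`` is a constant drive (zero by default).  ``control`` records
    the dose-like parameter the term heights were resolved at.
    """

    terms: list[GaussianTerm]
    d: int
    control: float = 0.0
    tilt: np.ndarray | None = None
    bowl_center: np.ndarray | None = None
    bowl_kappa: float = 0.0

    def energy(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        U = np.zeros(X.shape[:-1])
        for t in self.terms:
            U = U + t.energy(X)
        if self.bowl_kappa:
            U = U + self.bowl_kappa * np.sum((X - self.bowl_center) ** 2, axis=-1)
        if self.tilt is not None:
            U = U + X @ np.asarray(self.tilt)
        return U

    def gradient(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        g = np.zeros_like(X)
        for t in self.terms:
            g = g + t.gradient(X)
        if self.bowl_kappa:
            g = g + 2.0 * self.bowl_kappa * (X - self.bowl_center)
        if self.tilt is not None:
            g = g + np.asarray(self.tilt)
        return g


@dataclass
class SimulationConfig:
    """Euler-Maruyama integration settings.

    ``dt_sim`` is the integrator step; frames are recorded every ``thin``
    steps so the observation interval is ``thin * dt_sim`` (hours).  ``init``
    is either a d-vector (point start) or a ``(mean, sigma)`` pair for a
    Gaussian cloud.  A fixed seed gives a bitwise-reproducible ensemble.
    """

    n_traj: int
    n_steps: int
    dt_sim: float
    noise_sigma: float | np.ndarray
    init: object
    seed: int
    thin: int = 1
    bound: float = 1e3

    def __post_init__(self) -> None:
        if self.n_traj < 1 or self.n_steps < 1:
            raise ValidationError("n_traj and n_steps must be >= 1")
        if np.any(np.asarray(self.noise_sigma) < 0):
            raise ValidationError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Two-channel landscape

TWO_PATH_E_CENTER = np.array([0.0, 0.0])
TWO_PATH_M_CENTER = np.array([20.0, 15.0])

# Control schedule for the destabilization: the E well flattens by
# control=0.55; the concerted-channel saddle is gone by 0.45, the
# texture-first saddle only at 1.0 -> sequential saddle-node collisions.
_E_DEPTH0 = 30.0
_H1_0 = 20.0  # texture-first channel saddle (vanishes at control=1)
_H2_0 = 16.0  # concerted channel saddle (vanishes at control=0.45)
_S1 = (0.8, 4.2)
_S2 = (5.6, 4.2)


def _two_path_terms(control: float, e_center: np.ndarray) -> list[GaussianTerm]:
    dE = _E_DEPTH0 * max(1.0 - control / 0.55, 0.0)
    h1 = _H1_0 * max(1.0 - control, 0.0)
    h2 = _H2_0 * max(1.0 - control / 0.45, 0.0)
    terms = [
        GaussianTerm(tuple(e_center), -dE, (2.5, 2.5)),
        # dose-driven bias toward the texture axis: engages once the E well
        # has collapsed (control > 0.5); wide and shallow so it steers the E
        # exit toward the texture-first channel without creating a deep
        # intermediate trap
        GaussianTerm((1.5, 6.5), -16.0 * max(control - 0.5, 0.0), (4.5, 4.5)),
        GaussianTerm((20.0, 15.0), -25.0, (4.0, 4.0)),
        GaussianTerm((20.0, 15.0), -36.0, (30.0, 30.0)),  # broad pull toward M
        GaussianTerm(_S1, h1, (1.5, 1.5)),
        GaussianTerm(_S2, h2, (1.5, 1.5)),
        # texture-first trench: an elliptical arc rising along the texture
        # axis before bending toward M, with a steadily deepening profile
        GaussianTerm((2.2, 6.8), -10.0, (3.0, 3.0)),
        GaussianTerm((4.8, 9.7), -13.0, (3.0, 3.0)),
        GaussianTerm((8.2, 12.1), -16.0, (3.0, 3.0)),
        GaussianTerm((12.3, 13.9), -20.0, (3.0, 3.0)),
        GaussianTerm((16.9, 14.8), -25.0, (3.0, 3.0)),
        # concerted trench: along the diagonal beyond its saddle, with a
        # rugged profile that slows passage so both channels carry
        # comparable per-frame transition probabilities
        GaussianTerm((8.0, 6.0), -12.0, (1.5, 1.5)),
        GaussianTerm((11.0, 8.25), -12.0, (1.5, 1.5)),
        GaussianTerm((14.0, 10.5), -12.0, (1.5, 1.5)),
        GaussianTerm((17.0, 12.75), -12.0, (1.5, 1.5)),
        # ridge separating the channels, and outer walls
        GaussianTerm((6.5, 9.8), 18.0, (1.2, 1.2)),
        GaussianTerm((-4.5, 7.0), 15.0, (2.5, 2.5)),
        GaussianTerm((10.0, 2.0), 15.0, (2.5, 2.5)),
        GaussianTerm((10.0, -10.0), 40.0, (12.0, 4.5)),  # southern wall
    ]
    return terms


def make_two_path_potential(control: float) -> PotentialSpec:
    """Two-channel EMT-like landscape at a given dose-like control in [0, 1].

    At control=0 the epithelial well is a strict local minimum (the well term
    is re-centred so the composite landscape is stationary exactly at the
    nominal E centre); increasing control lowers both channel barriers, the
    concerted one first; at control=1 no local minimum survives near E and
    both channel centerlines run downhill out of E.
    """
    if not 0.0 <= control <= 1.0:
        raise ValueError(f"control must lie in [0, 1], got {control}")

    # Re-centre the E well so grad U = 0 exactly at the nominal E centre for
    # the control=0 landscape (the surrounding terms exert a small pull).
    def resid(c_e):
        spec = PotentialSpec(
            _two_path_terms(0.0, np.asarray(c_e)),
            d=2,
            bowl_center=np.array([10.0, 7.5]),
            bowl_kappa=0.02,
        )
        return spec.gradient(TWO_PATH_E_CENTER)[0]

    sol = optimize.root(resid, TWO_PATH_E_CENTER, tol=1e-12)
    e_center = sol.x
    return PotentialSpec(
        _two_path_terms(control, e_center),
        d=2,
        control=control,
        bowl_center=np.array([10.0, 7.5]),
        bowl_kappa=0.02,
    )


def two_path_regions(E_radius: float = 3.5, M_radius: float = 5.0):
    """E/M region geometry matching the two-channel landscape.

    E is centred at the nominal epithelial centre; M at the landscape's
    actual mesenchymal minimum (the trench and broad-pull terms shift it off
    the nominal M well centre).
    """
    from scipy import optimize as _opt

    from .regions import RegionSpec

    spec = make_two_path_potential(1.0)
    res = _opt.minimize(
        lambda x: spec.energy(x)[0],
        TWO_PATH_M_CENTER,
        jac=lambda x: spec.gradient(x)[0],
    )
    return RegionSpec(TWO_PATH_E_CENTER.copy(), res.x, E_radius, M_radius)


def channel_centerline(channel: int, n: int = 200) -> np.ndarray:
    """Reference centerline of a transition channel, E to M, (n, 2).

    Channel 1 ("texture-first") climbs the texture-like axis before moving the
    morphology-like axis; channel 2 ("concerted") is the straight diagonal.
    """
    t = np.linspace(0.0, 1.0, n)
    if channel == 1:
        phi = 0.5 * np.pi * t
        x = 20.0 * (1.0 - np.cos(phi))
        y = 15.0 * np.sin(phi)
        return np.column_stack([x, y])
    if channel == 2:
        return np.outer(t, TWO_PATH_M_CENTER - TWO_PATH_E_CENTER) + TWO_PATH_E_CENTER
    raise ValueError("channel must be 1 or 2")


def channel_barriers(spec: PotentialSpec, n: int = 400) -> tuple[float, float]:
    """Barrier of each channel: max U along its centerline minus U(E centre).

    Only the approach segment (before the channel enters the M basin) is
    scanned, so the M-well depth does not mask the saddle region.
    """
    U_e = float(spec.energy(TWO_PATH_E_CENTER)[0])
    out = []
    for ch in (1, 2):
        line = channel_centerline(ch, n)
        keep = np.linalg.norm(line - TWO_PATH_M_CENTER, axis=1) > 6.0
        U = spec.energy(line[keep])
        out.append(float(U.max() - U_e))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Langevin integration


def _draw_init(config: SimulationConfig, d: int, rng: np.random.Generator) -> np.ndarray:
    init = config.init
    if isinstance(init, tuple) and len(init) == 2 and np.ndim(init[1]) <= 1:
        mean, sigma = init
        mean = np.broadcast_to(np.asarray(mean, float), (d,))
        sigma = np.broadcast_to(np.asarray(sigma, float), (d,))
        return mean + sigma * rng.standard_normal((config.n_traj, d))
    point = np.asarray(init, dtype=float).reshape(-1)
    return np.tile(point, (config.n_traj, 1))


def simulate_langevin(
    potential,
    config: SimulationConfig,
    feature_names: list[str] | None = None,
    condition_label: str = "",
) -> TrajectoryEnsemble:
    """Integrate ``dx = -grad U dt + sigma sqrt(dt) xi`` for an ensemble.

    All trajectories advance in lockstep (vectorized Euler-Maruyama).  A
    trajectory whose norm exceeds ``config.bound`` is flagged: it is dropped
    from the returned ensemble and listed in ``ensemble.divergent`` with a
    warning, never silently NaN.
    """
    d = potential.d
    rng = np.random.default_rng(config.seed)
    x = _draw_init(config, d, rng)
    sigma = np.broadcast_to(np.asarray(config.noise_sigma, float), (d,))
    sqdt = np.sqrt(config.dt_sim)

    n_frames = config.n_steps // config.thin + 1
    frames = np.empty((config.n_traj, n_frames, d))
    frames[:, 0] = x
    fi = 1
    for k in range(1, config.n_steps + 1):
        x = x - potential.gradient(x) * config.dt_sim
        if np.any(sigma > 0):
            x = x + sigma * sqdt * rng.standard_normal((config.n_traj, d))
        if k % config.thin == 0:
            frames[:, fi] = x
            fi += 1

    dt_obs = config.dt_sim * config.thin
    times = np.arange(n_frames) * dt_obs
    names = feature_names or [f"pc{i + 1}" for i in range(d)]
    keep, divergent = [], []
    for i in range(config.n_traj):
        if np.max(np.abs(frames[i])) > config.bound or not np.all(
            np.isfinite(frames[i])
        ):
            divergent.append(f"sim{i:04d}")
            continue
        keep.append(FeatureTrajectory(f"sim{i:04d}", times.copy(), frames[i]))
    if divergent:
        warnings.warn(
            f"{len(divergent)} trajectories diverged beyond |x| > {config.bound} "
            "and were dropped",
            stacklevel=2,
        )
    if not keep:
        raise ValidationError("all trajectories diverged")
    ens = TrajectoryEnsemble(keep, names, dt_obs, condition_label)
    ens.divergent = divergent  # type: ignore[attr-defined]
    return ens


# Default observation settings for the two-channel fixture: integrator step
# 0.0025 h, one recorded frame every 0.4 h, 36 h of recording (the recording
# window is transit-dominated, as in a time-lapse study that ends shortly
# after most cells have completed the transition).
TWO_PATH_SIM = dict(dt_sim=0.0025, thin=160, n_steps=14400, noise_sigma=1.5)


def simulate_two_path_ensemble(
    n_per_channel: int = 60,
    control: float = 1.0,
    seed: int = 0,
    **overrides,
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Labeled two-channel ensemble: ``n_per_channel`` trajectories per path.

    Ground-truth channel membership is generative: each half is integrated on
    the landscape with the *other* channel's entrance blocked by a tall bump,
    so a trajectory can only transit through its assigned channel.  Returns
    the merged ensemble and the channel labels (1 or 2).
    """
    base = make_two_path_potential(control)
    sim_kw = {**TWO_PATH_SIM, **overrides}
    halves = []
    for ch, blocked_at in ((1, _S2), (2, _S1)):
        spec = PotentialSpec(
            base.terms + [GaussianTerm(blocked_at, 60.0, (2.5, 2.5))],
            d=2,
            control=control,
            bowl_center=base.bowl_center,
            bowl_kappa=base.bowl_kappa,
        )
        cfg = SimulationConfig(
            n_traj=n_per_channel,
            init=(TWO_PATH_E_CENTER, 0.8),
            seed=seed * 2 + ch,
            **sim_kw,
        )
        ens = simulate_langevin(
            spec, cfg, feature_names=["morph_pc1", "texture_pc1"],
            condition_label=f"control={control:g}",
        )
        for tr in ens.trajectories:
            tr.cell_id = f"ch{ch}_{tr.cell_id}"
        halves.append(ens)
    merged = TrajectoryEnsemble(
        halves[0].trajectories + halves[1].trajectories,
        halves[0].feature_names,
        halves[0].dt,
        halves[0].condition_label,
    )
    labels = np.array([1] * len(halves[0]) + [2] * len(halves[1]))
    return merged, labels


# ---------------------------------------------------------------------------
# Discrete-chain and PCA fixtures


def make_markov_fixture(
    P: np.ndarray, n_traj: int, n_steps: int, seed: int, init: np.ndarray | None = None
) -> list[np.ndarray]:
    """Sample i.i.d. state sequences from a row-stochastic matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("P must be square")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
        raise ValidationError("P rows must be non-negative and sum to 1")
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    if init is None:
        start = rng.integers(0, n, size=n_traj)
    else:
        start = rng.choice(n, size=n_traj, p=np.asarray(init, float))
    chains = []
    u = rng.random((n_traj, n_steps))
    for i in range(n_traj):
        seq = np.empty(n_steps + 1, dtype=np.int64)
        seq[0] = start[i]
        for t in range(n_steps):
            seq[t + 1] = np.searchsorted(cum[seq[t]], u[i, t], side="right")
        chains.append(seq)
    return chains


def make_pca_fixture(D: int, d: int, seed: int) -> PCAModel:
    """Random orthonormal loadings plus a random mean (QR of a Gaussian)."""
    if d > D:
        raise ValueError(f"d={d} must not exceed D={D}")
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((D, d)))
    Q = Q * np.sign(np.diag(R))  # deterministic sign convention
    return PCAModel(mean=rng.standard_normal(D), loadings=Q)


# ---------------------------------------------------------------------------
# 1-D analytic landscapes for parameter-recovery fixtures


@dataclass
class _Analytic1D:
    U: object
    dU: object
    d: int = 1

    def energy(self, X):
        return self.U(np.atleast_2d(X)[..., 0])

    def gradient(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return self.dU(X[..., 0])[..., None]


def quadratic_well(curvature: float = 1.0) -> _Analytic1D:
    """U(s) = curvature * s^2 / 2 (the OU landscape)."""
    return _Analytic1D(
        U=lambda s: 0.5 * curvature * s**2, dU=lambda s: curvature * s
    )


def quartic_double_well(barrier: float = 1.0, well: float = 1.0) -> _Analytic1D:
    """U(s) = barrier * ((s/well)^2 - 1)^2: wells at +-well, barrier at 0."""
    return _Analytic1D(
        U=lambda s: barrier * ((s / well) ** 2 - 1.0) ** 2,
        dU=lambda s: 4.0 * barrier * s * ((s / well) ** 2 - 1.0) / well**2,
    )
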