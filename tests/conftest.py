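import numpy as np
import pytest

from statepath import (
    FeatureTrajectory,
    SimulationConfig,
    TrajectoryEnsemble,
    extract_reactive,
    simulate_two_path_ensemble,
    two_path_regions,
)


@pytest.fixture(scope="session")
def two_path_data():
    """Reference two-channel ensemble at full destabilization (control=1):
    60 trajectories per generative channel, with ground-truth labels and the
    reactive subset.  Shared across the discovery-chain tests."""
    ensemble, truth = simulate_two_path_ensemble(
        n_per_channel=60, control=1.0, seed=5
    )
    regions = two_path_regions()
    reactive = extract_reactive(ensemble, regions, deadline=48.0)
    ids = {tr.cell_id for tr in reactive}
    truth_reactive = np.array(
        [lab for tr, lab in zip(ensemble, truth) if tr.cell_id in ids]
    )
    return {
        "ensemble": ensemble,
        "truth": truth,
        "regions": regions,
        "reactive": reactive,
        "truth_reactive": truth_reactive,
    }


@pytest.fixture(scope="session")
def quarter_circle_data():
    """Trajectories fluctuating around a quarter-circle arc of radius 10
    (noise sigma=0.5), with ball regions at the arc ends."""
    from statepath import RegionSpec

    rng = np.random.default_rng(42)
    T = 40
    trajs = []
    for i in range(100):
        theta = np.linspace(0.0, np.pi / 2, T)
        pts = np.column_stack(
            [10 * np.cos(theta), 10 * np.sin(theta)]
        ) + rng.normal(0, 0.5, (T, 2))
        trajs.append(FeatureTrajectory(f"arc{i:03d}", np.arange(T) * 0.5, pts))
    ensemble = TrajectoryEnsemble(trajs, ["x", "y"], 0.5)
    regions = RegionSpec(np.array([10.0, 0.0]), np.array([0.0, 10.0]), 1.5, 1.5)
    return ensemble, regions


@pytest.fixture()
def small_ensemble():
    """Tiny deterministic 2-cell ensemble for I/O and bookkeeping tests."""
    t = np.arange(4) * 0.25
    a = FeatureTrajectory("a", t, np.column_stack([np.arange(4.0), np.ones(4)]))
    b = FeatureTrajectory("b", t, np.column_stack([-np.arange(4.0), np.zeros(4)]))
    return TrajectoryEnsemble([a, b], ["f1", "f2"], 0.25, condition_label="ctrl")


@pytest.fixture()
def ou_ensemble():
    """300 trajectories of the 1-D Ornstein-Uhlenbeck process U = s^2/2,
    sigma = 1, observed every 0.1 time units."""
    from statepath import quadratic_well, simulate_langevin

    cfg = SimulationConfig(
        n_traj=300, n_steps=2000, dt_sim=0.005, noise_sigma=1.0,
        init=(0.0, 1.0), seed=0, thin=20,
    )
    return simulate_langevin(quadratic_well(), cfg)
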