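import numpy as np
import pytest
from scipy import optimize, stats

from statepath import (
    SimulationConfig,
    make_markov_fixture,
    make_pca_fixture,
    make_two_path_potential,
    quadratic_well,
    simulate_langevin,
    simulate_two_path_ensemble,
)
from statepath.simulate import (
    TWO_PATH_E_CENTER,
    TWO_PATH_M_CENTER,
    channel_barriers,
    channel_centerline,
)


class TestTwoPathPotential:
    def test_control_zero_epithelial_attractor(self):
        """At zero dose the E centre is a strict local minimum: vanishing
        gradient and positive-definite Hessian."""
        spec = make_two_path_potential(0.0)
        g = spec.gradient(TWO_PATH_E_CENTER)[0]
        assert np.linalg.norm(g) < 1e-8
        eps = 1e-4
        H = np.zeros((2, 2))
        for i in range(2):
            e = np.zeros(2)
            e[i] = eps
            H[:, i] = (
                spec.gradient(TWO_PATH_E_CENTER + e)[0]
                - spec.gradient(TWO_PATH_E_CENTER - e)[0]
            ) / (2 * eps)
        assert np.all(np.linalg.eigvalsh(H) > 0)

    def test_control_one_no_minimum_near_E(self):
        """Full destabilization leaves no local minimum near the old E centre
        (dense multi-start minimization finds none within radius 3.5)."""
        spec = make_two_path_potential(1.0)
        starts = np.random.default_rng(0).uniform(-3, 3, size=(40, 2))
        for x0 in starts:
            res = optimize.minimize(
                lambda x: spec.energy(x)[0], x0, jac=lambda x: spec.gradient(x)[0]
            )
            if res.success and np.linalg.norm(spec.gradient(res.x)) < 1e-6:
                assert np.linalg.norm(res.x - TWO_PATH_E_CENTER) > 3.5

    def test_barriers_decrease_and_open_sequentially(self):
        """Both channel barriers decrease with control; the concerted channel
        opens first, the texture-first channel later."""
        controls = [0.0, 0.2, 0.4, 0.55, 0.7, 1.0]
        b1s, b2s = zip(*(channel_barriers(make_two_path_potential(c)) for c in controls))
        assert all(x >= y - 1e-9 for x, y in zip(b1s, b1s[1:]))
        assert all(x >= y - 1e-9 for x, y in zip(b2s, b2s[1:]))
        # intermediate regime: exactly one channel open
        b1, b2 = channel_barriers(make_two_path_potential(0.45))
        assert b2 <= 1e-9 < b1
        # fully destabilized: both open
        b1, b2 = channel_barriers(make_two_path_potential(1.0))
        assert b1 <= 1e-9 and b2 <= 1e-9

    def test_control_out_of_range(self):
        with pytest.raises(ValueError):
            make_two_path_potential(1.5)


class TestSimulateLangevin:
    def test_zero_noise_at_fixed_point_is_constant(self):
        spec = make_two_path_potential(0.0)
        cfg = SimulationConfig(n_traj=1, n_steps=50, dt_sim=0.002,
                               noise_sigma=0.0, init=TWO_PATH_E_CENTER, seed=0)
        ens = simulate_langevin(spec, cfg)
        expected = np.tile(TWO_PATH_E_CENTER, (ens.trajectories[0].n_frames, 1))
        np.testing.assert_allclose(ens.trajectories[0].X, expected, atol=1e-12)

    def test_zero_noise_quadratic_well_matches_euler_closed_form(self):
        """x_{k+1} = x_k (1 - dt) exactly for U = |x|^2/2 without noise."""
        cfg = SimulationConfig(n_traj=1, n_steps=20, dt_sim=0.05,
                               noise_sigma=0.0, init=(np.array([2.0]), 0.0), seed=0)
        ens = simulate_langevin(quadratic_well(), cfg)
        expected = 2.0 * (1 - 0.05) ** np.arange(21)
        np.testing.assert_allclose(ens.trajectories[0].X[:, 0], expected, rtol=1e-12)

    def test_ou_stationary_variance(self):
        """Long-run variance of the discretized OU process matches sigma^2/2
        within 3 standard errors."""
        cfg = SimulationConfig(n_traj=50, n_steps=4000, dt_sim=0.01,
                               noise_sigma=1.0, init=(0.0, 0.0), seed=9, thin=4)
        ens = simulate_langevin(quadratic_well(), cfg)
        x = np.concatenate([tr.X[tr.n_frames // 4:, 0] for tr in ens])
        # discrete-time OU: var = sigma^2 dt / (1 - (1-dt)^2) ~ sigma^2/2
        target = 0.01 / (1 - (1 - 0.01) ** 2)
        se = target * np.sqrt(2.0 / 200)  # conservative effective sample size
        assert abs(x.var() - target) < 3 * se

    def test_seed_determinism(self):
        spec = make_two_path_potential(0.5)
        cfg = SimulationConfig(n_traj=3, n_steps=100, dt_sim=0.002,
                               noise_sigma=1.0, init=(TWO_PATH_E_CENTER, 0.5), seed=4)
        e1 = simulate_langevin(spec, cfg)
        e2 = simulate_langevin(spec, cfg)
        for t1, t2 in zip(e1, e2):
            np.testing.assert_array_equal(t1.X, t2.X)

    def test_quadratic_well_stationary_density_is_gaussian(self):
        """KS distance between long-run samples and the exact Gaussian
        stationary law stays below 0.05."""
        cfg = SimulationConfig(n_traj=100, n_steps=2000, dt_sim=0.01,
                               noise_sigma=1.0, init=(0.0, 0.7071), seed=2, thin=2)
        ens = simulate_langevin(quadratic_well(), cfg)
        x = np.concatenate([tr.X[tr.n_frames // 2:, 0] for tr in ens])
        ks = stats.kstest(x, "norm", args=(0.0, np.sqrt(0.5))).statistic
        assert ks < 0.05

    def test_divergent_trajectories_flagged_not_nan(self):
        # inverted quadratic well: deterministic blow-up
        class Inverted:
            d = 1
            def gradient(self, X):
                return -np.atleast_2d(X)
        cfg = SimulationConfig(n_traj=2, n_steps=200, dt_sim=0.1, noise_sigma=0.0,
                               init=(np.array([1.0]), 0.5), seed=1, bound=100.0)
        with pytest.warns(UserWarning, match="diverged"):
            with pytest.raises(Exception):
                simulate_langevin(Inverted(), cfg)


class TestTwoPathEnsemble:
    def test_labeled_channels_follow_their_corridors(self, two_path_data):
        """Blocked-channel generation keeps each trajectory nearer its own
        channel centerline through the intermediate region."""
        ens, truth = two_path_data["ensemble"], two_path_data["truth"]
        c1, c2 = channel_centerline(1, 300), channel_centerline(2, 300)
        M = two_path_data["regions"].M_center  # actual mesenchymal attractor
        correct = 0
        total = 0
        for tr, lab in zip(ens, truth):
            mid = tr.X[
                (np.linalg.norm(tr.X - TWO_PATH_E_CENTER, axis=1) > 4)
                & (np.linalg.norm(tr.X - M, axis=1) > 5)
            ]
            if len(mid) == 0:
                continue
            d1 = np.min(np.linalg.norm(mid[:, None] - c1[None], axis=2), axis=1).mean()
            d2 = np.min(np.linalg.norm(mid[:, None] - c2[None], axis=2), axis=1).mean()
            correct += (1 if d1 < d2 else 2) == lab
            total += 1
        assert correct / total >= 0.85

    def test_most_trajectories_reach_M(self, two_path_data):
        regions = two_path_data["regions"]
        reached = [
            np.any(np.linalg.norm(tr.X - regions.M_center, axis=1) <= regions.M_radius)
            for tr in two_path_data["ensemble"]
        ]
        assert np.mean(reached) > 0.75


class TestMarkovFixture:
    def test_identity_matrix_gives_constant_chains(self):
        chains = make_markov_fixture(np.eye(3), n_traj=5, n_steps=20, seed=0)
        for c in chains:
            assert len(set(c.tolist())) == 1

    def test_symmetric_two_state_counts_within_binomial_ci(self):
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        chains = make_markov_fixture(P, n_traj=10, n_steps=500, seed=1)
        flips = np.concatenate([c[:-1] != c[1:] for c in chains])
        n = len(flips)
        assert abs(flips.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(Exception):
            make_markov_fixture(np.array([[0.5, 0.4], [0.5, 0.5]]), 1, 1, 0)


class TestPCAFixture:
    def test_square_case_is_perfect_round_trip(self):
        pca = make_pca_fixture(D=4, d=4, seed=0)
        x = np.arange(4.0)
        np.testing.assert_allclose(
            pca.inverse_transform(pca.transform(x))[0], x, atol=1e-10
        )

    def test_loadings_orthonormal(self):
        pca = make_pca_fixture(D=9, d=4, seed=5)
        np.testing.assert_allclose(
            pca.loadings.T @ pca.loadings, np.eye(4), atol=1e-8
        )

    def test_d_greater_than_D_rejected(self):
        with pytest.raises(ValueError):
            make_pca_fixture(D=3, d=5, seed=0)
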