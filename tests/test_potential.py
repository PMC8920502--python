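import numpy as np
import pytest

from statepath import (
    FeatureTrajectory,
    QuasiPotentialModel,
    SimulationConfig,
    TrajectoryEnsemble,
    ck_deviation,
    integrate_potential,
    make_markov_fixture,
    potential_from_density,
    quadratic_well,
    simulate_langevin,
    uniform_rc_1d,
)


def _ensemble_1d(sequences, dt=1.0):
    trajs = [
        FeatureTrajectory(f"c{i}", np.arange(len(seq)) * dt,
                          np.asarray(seq, float)[:, None])
        for i, seq in enumerate(sequences)
    ]
    return TrajectoryEnsemble(trajs, ["s"], dt)


class TestEstimators:
    def test_deterministic_traversal_gives_minus_velocity(self):
        """One cell per frame toward M at speed v: grad = -v everywhere
        visited, diffusion = 0."""
        rc = uniform_rc_1d(0.0, 9.0, 10)  # ds = 1
        ens = _ensemble_1d([np.arange(10.0)] * 6, dt=1.0)
        qp = QuasiPotentialModel(ens, rc, min_count=5).fit()
        visited = qp.counts >= 5
        np.testing.assert_allclose(qp.grad[visited], -1.0, atol=1e-12)
        np.testing.assert_allclose(qp.D[visited], 0.0, atol=1e-12)

    def test_stationary_jitter_within_cell_gives_zero(self):
        rc = uniform_rc_1d(0.0, 9.0, 10)
        seq = np.full(12, 4.0) + np.linspace(-0.1, 0.1, 12)
        qp = QuasiPotentialModel(_ensemble_1d([seq] * 3), rc).fit()
        cell = np.argmin(np.abs(qp.s_grid - rc.matched_s(np.array([[4.0]]))[0]))
        assert qp.grad[cell] == 0.0 and qp.D[cell] == 0.0

    def test_unextrapolated_rc_rejected(self):
        from statepath.string_method import ReactionCoordinate

        img = np.linspace(0, 1, 5)[:, None]
        rc = ReactionCoordinate(img, np.linspace(0, 1, 5), img[[0, -1]], n_extra=0)
        with pytest.raises(ValueError, match="extrapolated"):
            QuasiPotentialModel(_ensemble_1d([np.zeros(3)]), rc)

    def test_min_count_masks_sparse_cells(self):
        # cell at s=4 is visited often; the single hop through s=7 is not
        rc = uniform_rc_1d(0.0, 9.0, 10)
        seqs = [[4.0] * 8 + [7.0, 9.0]] * 2
        qp = QuasiPotentialModel(_ensemble_1d(seqs), rc, min_count=5).fit()
        dense = np.argmin(np.abs(qp.s_grid - rc.matched_s(np.array([[4.0]]))[0]))
        sparse = np.argmin(np.abs(qp.s_grid - rc.matched_s(np.array([[7.0]]))[0]))
        assert not qp.mask[dense]
        assert qp.mask[sparse]

    def test_ou_drift_slope_and_flat_diffusion(self, ou_ensemble):
        """OU fixture: the drift gradient is linear with unit slope and the
        diffusion profile is flat across interior cells."""
        rc = uniform_rc_1d(-1.8, 1.8, 25)
        qp = QuasiPotentialModel(ou_ensemble, rc).fit()
        ok = ~qp.mask
        x = qp.s_grid[ok] - qp.s_grid[0] - 1.8 + qp.ds  # arc -> physical s
        slope, _ = np.polyfit(x, qp.grad[ok], 1)
        assert abs(slope - 1.0) < 0.1
        dense = qp.counts >= 200
        D = qp.D[dense]
        assert D.std() / D.mean() < 0.3

    def test_pure_noise_diffusion_magnitude(self):
        """Independent Gaussian positions of variance sigma^2: the per-cell
        velocity sample is (s(X') - s_i)/dt with s_i fixed at the cell
        coordinate, so D = Var(ds/dt) is about sigma^2/dt^2."""
        rng = np.random.default_rng(8)
        dt, sigma = 0.5, 0.3
        seqs = [rng.normal(0, sigma, 60) for _ in range(20)]
        rc = uniform_rc_1d(-1.5, 1.5, 15)
        qp = QuasiPotentialModel(_ensemble_1d(seqs, dt=dt), rc).fit()
        ok = ~qp.mask
        d_mean = np.average(qp.D[ok], weights=qp.counts[ok])
        assert abs(d_mean - sigma**2 / dt**2) < 0.2 * sigma**2 / dt**2


class TestIntegratePotential:
    def test_constant_gradient_cumulative_sum(self):
        phi = integrate_potential(np.full(5, 2.0), ds=1.0)
        np.testing.assert_allclose(phi, [0, 2, 4, 6, 8, 10])

    def test_zero_gradient_flat(self):
        np.testing.assert_allclose(integrate_potential(np.zeros(4), 0.5), 0.0)

    def test_masked_interior_interpolated(self):
        grad = np.array([1.0, np.nan, 1.0])
        phi = integrate_potential(grad, 1.0)
        np.testing.assert_allclose(phi, [0, 1, 2, 3])

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            integrate_potential(np.full(3, np.nan), 1.0)

    def test_ou_end_to_end_quadratic(self, ou_ensemble):
        """Drift estimation + integration recovers U = s^2/2 with R^2 > 0.95."""
        rc = uniform_rc_1d(-1.8, 1.8, 25)
        qp = QuasiPotentialModel(ou_ensemble, rc).fit()
        ok = ~qp.mask
        s, phi = qp.s_grid[ok], qp.phi_cells[ok]
        coef = np.polyfit(s, phi, 2)
        resid = phi - np.polyval(coef, s)
        r2 = 1 - resid @ resid / np.sum((phi - phi.mean()) ** 2)
        assert r2 > 0.95


class TestPotentialFromDensity:
    def _rc(self):
        return uniform_rc_1d(0.5, 2.5, 3)  # interior cells at 0.5, 1.5, 2.5

    def test_uniform_counts_give_flat_potential(self):
        pts = np.repeat([[0.5], [1.5], [2.5]], 7, axis=0)
        phi0 = potential_from_density(pts, self._rc(), pseudocount=0.0)
        np.testing.assert_allclose(phi0, 0.0, atol=1e-12)

    def test_log_count_ratios(self):
        """Counts (90, 9, 1) with no pseudocount give consecutive potential
        differences log(10) and log(9)."""
        pts = np.concatenate(
            [np.full(90, 0.5), np.full(9, 1.5), np.full(1, 2.5)]
        )[:, None]
        phi0 = potential_from_density(pts, self._rc(), pseudocount=0.0)
        assert phi0[1] - phi0[0] == pytest.approx(np.log(10))
        assert phi0[2] - phi0[1] == pytest.approx(np.log(9))

    def test_gaussian_sample_is_quadratic(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, 40000)[:, None]
        rc = uniform_rc_1d(-2.5, 2.5, 21)
        phi0 = potential_from_density(pts, rc)
        s = np.linspace(-2.5, 2.5, 21)
        coef = np.polyfit(s, phi0, 2)
        resid = phi0 - np.polyval(coef, s)
        r2 = 1 - resid @ resid / np.sum((phi0 - phi0.mean()) ** 2)
        assert r2 > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            potential_from_density(np.zeros((0, 1)), self._rc())


class TestCKTest:
    def test_deterministic_cycle_has_zero_deviation(self):
        chains = [np.tile([0, 1, 2], 50) for _ in range(5)]
        res = ck_deviation(chains, 3, tau=1, ks=(2, 3, 4))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.deviations.values())

    def test_k1_deviation_exactly_zero(self):
        chains = make_markov_fixture(
            np.array([[0.7, 0.3], [0.4, 0.6]]), 10, 200, seed=0
        )
        res = ck_deviation(chains, 2)
        assert res.deviations[1] == 0.0

    def test_markov_chain_small_deviation(self):
        P = np.array([[0.90, 0.08, 0.02], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]])
        chains = make_markov_fixture(P, n_traj=100, n_steps=1000, seed=0)
        res = ck_deviation(chains, 3, tau=1, ks=(3,))
        assert res.deviations[3] < 0.1

    def test_lumped_chain_detected_as_non_markov(self):
        """Lumping two kinetically distinct states produces a CK violation
        well above the Markov fixture's bootstrap noise level."""
        P3 = np.array([[0.98, 0.02, 0.0], [0.40, 0.20, 0.40], [0.0, 0.10, 0.90]])
        chains = make_markov_fixture(P3, n_traj=100, n_steps=1000, seed=2)
        lumped = [np.where(c <= 1, 0, 1) for c in chains]
        res = ck_deviation(lumped, 2, tau=1, ks=(2, 3, 4, 5))
        assert res.deviations[3] > 0.05
        devs = [res.deviations[k] for k in (2, 3, 4, 5)]
        assert all(x <= y for x, y in zip(devs, devs[1:]))  # grows with lag


class TestResultsSurface:
    def test_summary_and_frame(self, ou_ensemble):
        rc = uniform_rc_1d(-1.8, 1.8, 25)
        qp = QuasiPotentialModel(ou_ensemble, rc).fit()
        text = qp.summary()
        assert "interior cells" in text and "diffusion" in text
        df = qp.to_frame()
        assert list(df.columns) == ["s", "grad", "grad_se", "phi", "D", "counts"]
        assert len(df) == len(qp.s_grid)
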