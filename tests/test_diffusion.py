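"""Stationary diffusions: drift decomposition, divergence, simulation."""

import numpy as np
import pytest

import bayesmech as bm
from bayesmech.presets import EXAMPLE_2_2_PRECISION, REMARK_3_2_Q

from conftest import random_blanket_density


@pytest.fixture
def state_dependent_model(example_density):
    """Q with a state-dependent entry Q_02 = x_1; analytic divergence known."""

    def q_field(x):
        Q = np.zeros((3, 3))
        Q[0, 2] = x[1]
        Q[2, 0] = -x[1]
        return Q

    def divergence_fn(x):
        # (div Q)_i = sum_j d/dx_j Q_ij; only Q_02 varies, with x_1 -> no
        # dependence on x_2, so the divergence of Q vanishes; Gamma is
        # constant. The analytic divergence is therefore zero.
        return np.zeros(3)

    return bm.DiffusionModel(
        density=example_density,
        sigma_field=lambda x: np.eye(3),
        q_field=q_field,
        divergence_mode="analytic",
        divergence_fn=divergence_fn,
    )


class TestDriftField:
    def test_printed_drift_matrix(self, remark_model):
        # the worked constant-coefficient drift: dx = -(printed matrix) x dt + dW
        printed = np.array([[1.0, 1.5, 2.0], [0.5, 1.0, 0.5], [-2.0, -0.5, 1.0]])
        np.testing.assert_allclose(remark_model.drift_matrix(), -printed, atol=1e-12)
        np.testing.assert_allclose(
            bm.drift_field(remark_model, [1.0, 0.0, 0.0]), [-1.0, -0.5, 2.0]
        )

    def test_drift_vanishes_at_mean_for_constant_fields(self, remark_model):
        np.testing.assert_allclose(
            bm.drift_field(remark_model, remark_model.density.mean), 0.0, atol=1e-14
        )

    def test_state_dependent_drift_matches_finite_differences(self, example_density):
        def q_field(x):
            Q = np.zeros((3, 3))
            Q[0, 2] = np.sin(x[1]) + x[0]
            Q[2, 0] = -Q[0, 2]
            return Q

        fd = bm.DiffusionModel(
            density=example_density,
            sigma_field=lambda x: np.eye(3),
            q_field=q_field,
            divergence_mode="finite_difference",
        )

        def divergence_fn(x):
            # only Q_02(x) = sin(x_1) + x_0 varies: (div)_0 = dQ_02/dx_2 = 0,
            # (div)_2 = dQ_20/dx_0 = -1
            return np.array([0.0, 0.0, -1.0])

        an = bm.DiffusionModel(
            density=example_density,
            sigma_field=lambda x: np.eye(3),
            q_field=q_field,
            divergence_mode="analytic",
            divergence_fn=divergence_fn,
        )
        x = np.array([0.3, -1.2, 0.7])
        np.testing.assert_allclose(
            bm.drift_field(fd, x), bm.drift_field(an, x), atol=1e-6
        )


class TestDivergence:
    def test_constant_fields_zero(self, remark_model):
        np.testing.assert_array_equal(
            bm.divergence_term(remark_model, [1.0, 2.0, 3.0]), np.zeros(3)
        )

    def test_finite_difference_recovers_hand_value(self, example_density):
        # Q_02 = x_1 (antisymmetric partner Q_20 = -x_1):
        # (div)_0 = dQ_02/dx_2 = 0; (div)_2 = dQ_20/dx_0 = 0; exact zero,
        # but make Q_01 = x_1 so (div)_0 = dQ_01/dx_1 = 1, (div)_1 = -0.
        def q_field(x):
            Q = np.zeros((3, 3))
            Q[0, 1] = x[1]
            Q[1, 0] = -x[1]
            return Q

        model = bm.DiffusionModel(
            density=example_density,
            sigma_field=lambda x: np.eye(3),
            q_field=q_field,
            divergence_mode="finite_difference",
        )
        div = bm.divergence_term(model, [0.5, 0.25, -1.0])
        np.testing.assert_allclose(div, [1.0, 0.0, 0.0], atol=1e-6)

    def test_analytic_vs_finite_difference_on_quadratic_field(self, example_density):
        def q_field(x):
            Q = np.zeros((3, 3))
            Q[0, 2] = x[1] ** 2
            Q[2, 0] = -(x[1] ** 2)
            return Q

        fd = bm.DiffusionModel(
            density=example_density, sigma_field=lambda x: np.eye(3),
            q_field=q_field, divergence_mode="finite_difference",
        )
        # quadratic field: central differences are exact up to O(h^2) rounding
        div = bm.divergence_term(fd, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(div, [0.0, 0.0, 0.0], atol=1e-8)

    def test_analytic_mode_requires_function(self, example_density):
        with pytest.raises(ValueError, match="divergence_fn"):
            bm.DiffusionModel(
                density=example_density,
                sigma_field=lambda x: np.eye(3),
                q_field=lambda x: np.zeros((3, 3)),
                divergence_mode="analytic",
            )


class TestModelValidation:
    def test_rejects_non_antisymmetric_q(self, example_density):
        with pytest.raises(ValueError, match="antisymmetric"):
            bm.DiffusionModel(density=example_density, q_field=np.eye(3))

    def test_zero_volatility_is_legal(self, example_density):
        model = bm.DiffusionModel(
            density=example_density, sigma_field=np.zeros((3, 3)),
            q_field=REMARK_3_2_Q,
        )
        assert model.constant_fields


class TestStationarityResidual:
    def test_remark_model_residual_is_zero(self, remark_model):
        assert np.abs(bm.stationarity_residual(remark_model)).max() < 1e-12

    def test_pure_gradient_flow_residual_is_zero(self, example_density):
        model = bm.DiffusionModel(density=example_density, sigma_field=np.eye(3))
        assert np.abs(bm.stationarity_residual(model)).max() < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_random_constant_models_satisfy_lyapunov(self, seed):
        density = random_blanket_density(seed)
        d = density.d
        rng = np.random.default_rng(seed + 99)
        A = rng.standard_normal((d, d))
        model = bm.DiffusionModel(
            density=density, sigma_field=rng.standard_normal((d, d)),
            q_field=(A - A.T) / 2.0,
        )
        scale = np.abs(model.drift_matrix()).max()
        assert np.abs(bm.stationarity_residual(model)).max() < 1e-10 * scale

    def test_perturbed_drift_breaks_identity(self, remark_model):
        B = remark_model.drift_matrix() + 0.3 * np.eye(3)
        S = remark_model.density.covariance
        resid = B @ S + S @ B.T + np.eye(3)
        assert np.abs(resid).max() > 0.1

    def test_state_dependent_model_unsupported(self, state_dependent_model):
        with pytest.raises(ValueError):
            bm.stationarity_residual(state_dependent_model)


class TestTransitionMoments:
    def test_limits(self, remark_model):
        x0 = np.array([1.0, -2.0, 0.5])
        mean0, cov0 = bm.ou_transition_moments(remark_model, x0, 0.0)
        np.testing.assert_allclose(mean0, x0)
        np.testing.assert_allclose(cov0, 0.0, atol=1e-14)
        mean_inf, cov_inf = bm.ou_transition_moments(remark_model, x0, 50.0)
        np.testing.assert_allclose(mean_inf, 0.0, atol=1e-9)
        np.testing.assert_allclose(cov_inf, remark_model.density.covariance, atol=1e-9)

    def test_simulated_moments_match_closed_form(self, remark_model):
        t, dt, n = 0.5, 1e-3, 20_000
        ens = bm.simulate(remark_model, np.array([1.0, 0.0, 0.0]), dt, t,
                          n_paths=n, seed=8, record_every=int(t / dt))
        X = ens.paths[:, -1, :]
        mean, cov = bm.ou_transition_moments(remark_model, [1.0, 0.0, 0.0], t)
        se_mean = np.sqrt(np.diag(cov) / n)
        assert (np.abs(X.mean(axis=0) - mean) < 5 * se_mean + 5e-3).all()
        C = np.cov(X.T)
        se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / n)
        assert (np.abs(C - cov) < 5 * se_cov + 5e-3).all()


class TestSimulate:
    def test_deterministic_given_seed(self, remark_model):
        a = bm.simulate(remark_model, "stationary", 0.01, 1.0, n_paths=3, seed=5)
        b = bm.simulate(remark_model, "stationary", 0.01, 1.0, n_paths=3, seed=5)
        np.testing.assert_array_equal(a.paths, b.paths)

    def test_noise_free_conservative_flow_preserves_quadratic_form(self, example_density):
        # sigma = 0: deterministic solenoidal flow along contours of p,
        # so x^T Pi x is a conserved quantity.
        model = bm.DiffusionModel(
            density=example_density, sigma_field=np.zeros((3, 3)),
            q_field=REMARK_3_2_Q,
        )
        x0 = np.array([1.0, 0.5, -0.5])
        ens = bm.simulate(model, x0, dt=1e-3, t_end=10.0, seed=0, method="rk4")
        Pi = example_density.precision
        energies = np.einsum("ti,ij,tj->t", ens.paths[0], Pi, ens.paths[0])
        assert np.abs(energies - energies[0]).max() < 1e-8 * energies[0]

    def test_one_step_preserves_stationary_covariance(self, remark_model):
        n = 10_000
        ens = bm.simulate(remark_model, "stationary", dt=1e-3, t_end=1e-3,
                          n_paths=n, seed=13)
        X = ens.paths[:, -1, :]
        S = remark_model.density.covariance
        se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S**2) / n)
        assert (np.abs(X.T @ X / n - S) < 5 * se + 0.01).all()

    def test_time_average_covariance_matches_stationary(self, remark_model):
        # single long trajectory; Frobenius-relative error of the
        # time-average second moment against Sigma
        ens = bm.simulate(remark_model, "stationary", dt=1e-3, t_end=2000.0,
                          n_paths=1, seed=2, record_every=10)
        X = ens.paths[0]
        C = X.T @ X / X.shape[0]
        S = remark_model.density.covariance
        assert np.linalg.norm(C - S) / np.linalg.norm(S) < 0.05

    def test_blow_up_detected(self, remark_model):
        # dt far beyond the stability limit: the explicit scheme diverges
        # and the integrator reports the offending step
        with pytest.raises(FloatingPointError, match="step"):
            bm.simulate(remark_model, [1.0, 1.0, 1.0], dt=5.0, t_end=5000.0, seed=1)

    def test_argument_validation(self, remark_model):
        with pytest.raises(ValueError):
            bm.simulate(remark_model, "stationary", dt=-0.1, t_end=1.0)
        with pytest.raises(ValueError):
            bm.simulate(remark_model, "stationary", dt=0.1, t_end=1.0, n_paths=0)

    def test_non_gaussian_transitions_gaussian_marginal(self):
        # Gaussian steady state does not mean Gaussian process: with
        # state-dependent volatility the transition density from a point
        # mass is strongly non-Gaussian, while the time-marginal stays
        # consistent with N(0, Sigma).
        from scipy import stats

        model = bm.get_preset("transition_nongaussian")
        ens = bm.simulate(model, np.zeros(3), dt=2e-3, t_end=0.5, n_paths=500,
                          seed=6, record_every=250)
        X_t = ens.paths[:, -1, :]
        pvals = [stats.normaltest(X_t[:, j]).pvalue for j in range(3)]
        assert max(pvals) < 1e-2

        long_run = bm.simulate(model, "stationary", dt=2e-3, t_end=200.0,
                               n_paths=1, seed=7, record_every=10)
        Y = long_run.paths[0]
        C = Y.T @ Y / Y.shape[0]
        S = model.density.covariance
        assert np.linalg.norm(C - S) / np.linalg.norm(S) < 0.2
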