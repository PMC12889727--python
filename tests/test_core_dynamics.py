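import json

import numpy as np
import numpy.testing as npt
import pytest

from dynml import (
    IntegratorConfig,
    LorenzEnsembleParams,
    NumericalDivergenceError,
    RosslerEnsembleParams,
    evolve_ensemble,
    lorenz_rhs,
    rossler_rhs,
    sample_lorenz_params,
    sample_rossler_params,
)
from dynml.core_dynamics import load_params, save_params


def single_lorenz(sigma=10.0, rho=28.0, beta=8.0 / 3.0, tau=1.0):
    return LorenzEnsembleParams(sigma=[sigma], rho=[rho], beta=[beta],
                                tau=[tau])


class TestVectorFields:
    @pytest.mark.parametrize(
        "state, tau, expected",
        [
            ((0.0, 0.0, 0.0), 1.0, (0.0, 0.0, 0.0)),  # origin is equilibrium
            ((1.0, 1.0, 1.0), 1.0, (0.0, 26.0, -5.0 / 3.0)),
            ((1.0, 1.0, 1.0), 2.0, (0.0, 13.0, -5.0 / 6.0)),
        ],
    )
    def test_lorenz_field_values(self, state, tau, expected):
        p = single_lorenz(tau=tau)
        npt.assert_allclose(lorenz_rhs(np.array(state), p), expected,
                            rtol=0, atol=1e-14)

    @pytest.mark.parametrize(
        "state, tau, expected",
        [
            ((0.0, 0.0, 0.0), 1.0, (0.0, 0.0, 0.2)),
            ((1.0, 1.0, 1.0), 1.0, (-2.0, 1.2, -4.5)),
            ((1.0, 1.0, 1.0), 2.0, (-1.0, 0.6, -2.25)),
        ],
    )
    def test_rossler_field_values(self, state, tau, expected):
        p = RosslerEnsembleParams(a=[0.2], b=[0.2], c=[5.7], tau=[tau])
        npt.assert_allclose(rossler_rhs(np.array(state), p), expected,
                            rtol=0, atol=1e-14)

    def test_dimension_mismatch_raises(self):
        p = single_lorenz()
        with pytest.raises(ValueError, match="3N"):
            lorenz_rhs(np.zeros(5), p)


class TestParameterSampling:
    def test_lorenz_ranges_contained(self):
        rng = np.random.default_rng(3)
        p = sample_lorenz_params(50, rng)
        assert np.all((p.sigma >= 9.9) & (p.sigma <= 10.1))
        assert np.all((p.rho >= 27.9) & (p.rho <= 28.1))
        assert np.all((p.beta >= 2.65) & (p.beta <= 2.70))
        assert np.all(p.tau > 0)

    def test_degenerate_interval(self):
        rng = np.random.default_rng(0)
        p = sample_lorenz_params(5, rng, sigma_range=(10.0, 10.0))
        npt.assert_array_equal(p.sigma, 10.0)

    def test_seed_determinism(self):
        p1 = sample_lorenz_params(8, np.random.default_rng(42))
        p2 = sample_lorenz_params(8, np.random.default_rng(42))
        for name in ("sigma", "rho", "beta", "tau"):
            npt.assert_array_equal(getattr(p1, name), getattr(p2, name))

    def test_rossler_jitter_containment(self):
        p = sample_rossler_params(30, np.random.default_rng(1))
        assert np.all((p.a >= 0.19) & (p.a <= 0.21))
        assert np.all((p.c >= 5.7 * 0.95) & (p.c <= 5.7 * 1.05))
        p0 = sample_rossler_params(3, np.random.default_rng(0), jitter=0.0)
        npt.assert_array_equal(p0.a, 0.2)
        npt.assert_array_equal(p0.c, 5.7)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            sample_lorenz_params(3, np.random.default_rng(0),
                                 sigma_range=(10.1, 9.9))

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            LorenzEnsembleParams(sigma=[10.0], rho=[28.0], beta=[2.7],
                                 tau=[0.0])


class TestEvolution:
    @pytest.mark.parametrize("method", ["rk4", "rk45"])
    def test_zero_fixed_point(self, method):
        """The origin is an equilibrium: zero stays exactly zero."""
        p = single_lorenz()
        cfg = IntegratorConfig(method=method, horizon=2.0)
        out = evolve_ensemble(np.zeros(3), p, cfg)
        npt.assert_array_equal(out, 0.0)

    def test_tau_rescaling_identity(self):
        """tau over horizon h matches tau=1 over h/tau (same dt/tau grid)."""
        x0 = np.array([1.0, 1.0, 1.0])
        f_tau = evolve_ensemble(
            x0, single_lorenz(tau=2.0),
            IntegratorConfig(horizon=30.0, dt=0.01))
        f_unit = evolve_ensemble(
            x0, single_lorenz(tau=1.0),
            IntegratorConfig(horizon=15.0, dt=0.005))
        npt.assert_allclose(f_tau, f_unit, rtol=0, atol=1e-6)

    def test_fixed_step_matches_fine_step_oracle(self):
        """dt=0.002 final state vs an independent dt=1e-5 RK4 oracle."""
        p = single_lorenz()
        x0 = np.array([1.0, 1.0, 1.0])
        out = evolve_ensemble(x0, p, IntegratorConfig(horizon=1.0, dt=0.002))

        def rhs(s):
            x, y, z = s
            return np.array([10.0 * (y - x), x * (28.0 - z) - y,
                             x * y - (8.0 / 3.0) * z])

        s = x0.astype(float)
        h = 1e-5
        for _ in range(100_000):
            k1 = rhs(s)
            k2 = rhs(s + 0.5 * h * k1)
            k3 = rhs(s + 0.5 * h * k2)
            k4 = rhs(s + h * k3)
            s = s + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        npt.assert_allclose(out, s, rtol=0, atol=1e-5)

    def test_adaptive_agrees_with_fixed_at_short_horizon(self):
        p = single_lorenz()
        x0 = np.array([0.3, -0.7, 0.5])
        cfg_fix = IntegratorConfig(method="rk4", horizon=1.0, dt=0.001)
        cfg_ada = IntegratorConfig(method="rk45", horizon=1.0,
                                   rtol=1e-9, atol=1e-12)
        npt.assert_allclose(evolve_ensemble(x0, p, cfg_fix),
                            evolve_ensemble(x0, p, cfg_ada),
                            rtol=0, atol=1e-4)

    def test_batch_equals_single_bitwise(self):
        rng = np.random.default_rng(7)
        p = sample_lorenz_params(4, rng)
        x0 = rng.normal(size=(5, 12))
        cfg = IntegratorConfig(horizon=3.0)
        batch = evolve_ensemble(x0, p, cfg)
        for d in range(5):
            npt.assert_array_equal(batch[d], evolve_ensemble(x0[d], p, cfg))

    def test_repeated_calls_bitwise_identical(self):
        rng = np.random.default_rng(9)
        p = sample_lorenz_params(3, rng)
        x0 = rng.normal(size=9)
        cfg = IntegratorConfig(horizon=5.0)
        npt.assert_array_equal(evolve_ensemble(x0, p, cfg),
                               evolve_ensemble(x0, p, cfg))

    def test_trajectory_endpoints_and_shape(self):
        p = single_lorenz()
        cfg = IntegratorConfig(horizon=1.0, dt=0.01, n_save=50)
        x0 = np.array([1.0, 1.0, 1.0])
        final, traj = evolve_ensemble(x0, p, cfg, want_trajectory=True)
        assert traj.shape == (51, 3)
        npt.assert_array_equal(traj[0], x0)
        npt.assert_array_equal(traj[-1], final)

    def test_divergence_guard(self):
        """A coarse step on a far-out Rössler state overflows; the error
        names the offending sample rather than returning NaNs."""
        p = RosslerEnsembleParams(a=[0.2], b=[0.2], c=[5.7], tau=[1.0])
        x0 = np.array([[0.1, 0.0, 0.0], [1e3, 1e3, 1e3]])
        with pytest.raises(NumericalDivergenceError, match="1"):
            evolve_ensemble(x0, p, IntegratorConfig(horizon=30.0, dt=0.5))

    def test_nonfinite_initial_state_rejected(self):
        p = single_lorenz()
        with pytest.raises(ValueError):
            evolve_ensemble(np.array([np.nan, 0.0, 0.0]), p)


def test_params_json_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    p = sample_lorenz_params(6, rng)
    path = tmp_path / "params.json"
    save_params(path, p, seed=5)
    q = load_params(path)
    npt.assert_array_equal(p.sigma, q.sigma)
    npt.assert_array_equal(p.tau, q.tau)
    assert json.loads(path.read_text())["seed"] == 5

    r = sample_rossler_params(4, rng)
    save_params(path, r)
    npt.assert_array_equal(load_params(path).c, r.c)
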