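"""SVR, PSO, PLS and cross-validation."""

import numpy as np
import pytest

from specmode import (CalibrationReport, PSOConfig, SpectraDataset, SVRHyper,
                      loocv, pls_fit, pls_predict, pso_optimize, pso_svr_fit,
                      rbf_kernel, svr_predict, svr_train)
from specmode.calibration import PSOResult, select_pls_components


class TestRbfKernel:
    def test_self_similarity_is_one(self):
        x = np.random.default_rng(0).standard_normal(5)
        assert rbf_kernel(x, x, 0.7) == pytest.approx(1.0)

    def test_distance_gamma_sqrt2_gives_exp_minus_one(self):
        g = 0.9
        xi = np.zeros(3)
        xj = np.array([g * np.sqrt(2.0), 0.0, 0.0])
        assert rbf_kernel(xi, xj, g) == pytest.approx(np.exp(-1.0))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = rng.standard_normal((2, 4))
            assert rbf_kernel(a, b, 1.3) == pytest.approx(rbf_kernel(b, a, 1.3))

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], 0.0)


class TestSvr:
    def test_constant_target_inside_tube(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 3))
        y = np.full(10, 4.2)
        model = svr_train(X, y, SVRHyper(epsilon=0.1, C=10.0, gamma=1.0))
        preds = svr_predict(model, X)
        assert np.all(np.abs(preds - 4.2) <= 0.1 + 1e-9)

    def test_interpolation_regime_on_line(self):
        x = np.linspace(0, 1, 15)[:, None]
        y = x.ravel()
        hyper = SVRHyper(epsilon=0.01, C=1e4, gamma=2.0)
        model = svr_train(x, y, hyper)
        preds = svr_predict(model, x)
        assert np.sqrt(np.mean((preds - y) ** 2)) < 2 * hyper.epsilon

    def test_dual_box_constraint(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        C = 5.0
        model = svr_train(X, y, SVRHyper(epsilon=0.05, C=C, gamma=1.0))
        assert np.all(np.abs(model.dual_coef) <= C + 1e-9)

    def test_duality_gap_small(self):
        # primal objective (with slack at the trained solution) must be
        # close to the dual objective reconstructed from the coefficients
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 3))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(25)
        hyper = SVRHyper(epsilon=0.05, C=10.0, gamma=1.0)
        model = svr_train(X, y, hyper)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        K = np.exp(-d2 / (2 * hyper.gamma ** 2))
        # expand dual coefficients to all samples
        beta = np.zeros(25)
        sv_idx = [int(np.argmin(((X - sv) ** 2).sum(1)))
                  for sv in model.support_vectors]
        beta[sv_idx] = model.dual_coef
        f = K @ beta + model.bias
        xi = np.maximum(0.0, np.abs(y - f) - hyper.epsilon)
        primal = 0.5 * beta @ K @ beta + hyper.C * np.sum(xi)
        dual = -0.5 * beta @ K @ beta - hyper.epsilon * np.sum(np.abs(beta)) \
            + y @ beta
        assert primal - dual < 1e-3 * max(1.0, abs(primal))

    def test_prediction_lipschitz_in_input(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 2))
        y = X[:, 0] ** 2
        hyper = SVRHyper(epsilon=0.01, C=100.0, gamma=1.0)
        model = svr_train(X, y, hyper)
        # |f'| <= sum|beta| * max_d |dK/dx| <= sum|beta| / (gamma*sqrt(e))
        L = np.sum(np.abs(model.dual_coef)) / (hyper.gamma * np.sqrt(np.e))
        x0 = np.zeros((1, 2))
        delta = 1e-4 * np.array([[1.0, 0.0]])
        df = abs(svr_predict(model, x0 + delta)[0] - svr_predict(model, x0)[0])
        assert df <= L * 1e-4 + 1e-12

    def test_dimension_mismatch(self):
        X = np.zeros((5, 3))
        y = np.arange(5.0)
        model = svr_train(X + np.random.default_rng(0).standard_normal((5, 3)),
                          y, SVRHyper())
        with pytest.raises(ValueError):
            svr_predict(model, np.zeros((2, 4)))


class TestPso:
    def test_sphere_benchmark(self):
        best = []
        for seed in range(20):
            res = pso_optimize(lambda p: float(np.sum(p ** 2)),
                               [(-5.0, 5.0), (-5.0, 5.0)],
                               PSOConfig(swarm_size=10, iter_max=100, seed=seed))
            best.append(res.fitness)
        assert np.median(best) < 1e-3

    def test_gbest_trace_nonincreasing(self):
        res = pso_optimize(lambda p: float(np.sum(np.abs(p))),
                           [(-3.0, 3.0)] * 3,
                           PSOConfig(swarm_size=6, iter_max=40, seed=1))
        assert np.all(np.diff(res.trace) <= 0)

    def test_positions_respect_bounds(self):
        seen = []
        def fitness(p):
            seen.append(p.copy())
            return float(p[0] ** 2)
        pso_optimize(fitness, [(2.0, 4.0)], PSOConfig(seed=0, iter_max=20))
        arr = np.array(seen)
        assert arr.min() >= 2.0 and arr.max() <= 4.0

    def test_nonfinite_fitness_recovered(self):
        def fitness(p):
            return np.inf if p[0] < 0 else float(p[0])
        res = pso_optimize(fitness, [(-1.0, 1.0)],
                           PSOConfig(seed=3, iter_max=30))
        assert np.isfinite(res.fitness)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            pso_optimize(lambda p: 0.0, [(0.0, np.inf)], PSOConfig(seed=0))


class TestPsoSvr:
    def test_recovers_linear_relationship(self):
        rng = np.random.default_rng(6)
        X = rng.random((20, 4))
        y = X @ np.array([1.0, -0.5, 0.3, 0.8])
        model, hyper, trace = pso_svr_fit(
            X, y, PSOConfig(seed=0, iter_max=15))
        preds = svr_predict(model, X)
        from specmode import r_coefficient
        assert r_coefficient(y, preds) > 0.999
        assert np.all(np.diff(trace) <= 0)
        assert 0.0 <= hyper.epsilon <= 0.2
        assert 1.0 <= hyper.C <= 1e8
        assert 0.01 <= hyper.gamma <= 2.0


class TestPls:
    def test_collinear_single_component(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 6))
        w = rng.standard_normal(6)
        y = X @ w
        # y in the span of X: rank-saturated PLS matches least squares
        model = pls_fit(X, y, 6)
        resid = pls_predict(model, X) - y
        assert np.max(np.abs(resid)) < 1e-6

    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(8)
        t = rng.standard_normal(10)
        X = np.outer(t, rng.standard_normal(5))
        y = 2.0 * t
        model = pls_fit(X, y, 1)
        assert np.max(np.abs(pls_predict(model, X) - y)) < 1e-8

    def test_component_cap_warns(self):
        X = np.random.default_rng(9).standard_normal((5, 3))
        y = np.arange(5.0)
        with pytest.warns(UserWarning):
            model = pls_fit(X, y, 10)
        assert model.n_components <= 3

    def test_component_selection_returns_valid_count(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 8))
        y = X[:, 0] + 0.01 * rng.standard_normal(12)
        k = select_pls_components(X, y, 5)
        assert 1 <= k <= 5


class TestLoocv:
    @staticmethod
    def dataset(n=15):
        rng = np.random.default_rng(11)
        wl = np.linspace(800, 2600, 30)
        conc = np.linspace(50, 1000, n)
        absorb = np.outer(conc / 1000, np.exp(-((wl - 1600) / 100) ** 2))
        absorb += 0.001 * rng.standard_normal(absorb.shape)
        return SpectraDataset(wavelengths=wl, absorbance=absorb,
                              concentrations=conc)

    def test_perfect_model_stub(self):
        ds = self.dataset()
        class Stub:
            def __init__(self, y): self.y = float(y)
        rep = loocv(ds,
                    lambda X, y: None,
                    lambda m, X: np.array([np.interp(
                        X[0, np.argmax(ds.absorbance.std(0))],
                        ds.absorbance[:, np.argmax(ds.absorbance.std(0))],
                        ds.concentrations)]))
        assert rep.r > 0.999

    def test_mean_predictor_gives_zero_r(self):
        ds = self.dataset()
        rep = loocv(ds,
                    lambda X, y: float(np.mean(y)),
                    lambda m, X: np.full(X.shape[0], m))
        assert rep.r == pytest.approx(0.0, abs=0.05)

    def test_fold_accounting(self):
        ds = self.dataset(15)
        sizes = []
        def fit(X, y):
            sizes.append(X.shape[0])
            return float(np.mean(y))
        loocv(ds, fit, lambda m, X: np.full(X.shape[0], m))
        assert len(sizes) == 15 and all(s == 14 for s in sizes)

    def test_failed_fold_marked_nan(self):
        ds = self.dataset(10)
        calls = {"i": 0}
        def fit(X, y):
            calls["i"] += 1
            if calls["i"] == 3:
                raise RuntimeError("boom")
            return float(np.mean(y))
        rep = loocv(ds, fit, lambda m, X: np.full(X.shape[0], m))
        assert np.isnan(rep.predictions).sum() == 1


class TestModelSerialization:
    def test_svr_roundtrip_predictions(self):
        from specmode.calibration import model_from_dict, model_to_dict
        rng = np.random.default_rng(12)
        X = rng.random((12, 5))
        y = X @ np.arange(1.0, 6.0)
        model = svr_train(X, y, SVRHyper(epsilon=0.01, C=100.0, gamma=1.0))
        back = model_from_dict(json_roundtrip(model_to_dict(model)))
        np.testing.assert_allclose(svr_predict(back, X),
                                   svr_predict(model, X), rtol=1e-12)

    def test_pls_roundtrip_predictions(self):
        from specmode.calibration import model_from_dict, model_to_dict
        rng = np.random.default_rng(13)
        X = rng.standard_normal((10, 6))
        y = X[:, 0] * 3.0 + 1.0
        model = pls_fit(X, y, 2)
        back = model_from_dict(json_roundtrip(model_to_dict(model)))
        np.testing.assert_allclose(pls_predict(back, X),
                                   pls_predict(model, X), atol=1e-10)


def json_roundtrip(d):
    import json
    return json.loads(json.dumps(d))
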