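"""Calibration models for NIR concentration prediction.

The quantitative model is ε-insensitive support vector regression with a
radial-basis kernel

    K(xi, xj) = exp(-||xi - xj||^2 / (2 γ^2)),

whose three hyperparameters — the tube half-width ε, the penalty C and
the kernel width γ — are selected jointly by particle swarm optimization
(PSO) with a cross-validated root-mean-square prediction error as the
fitness.  A PLS1 regression provides the classical linear baseline, and
leave-one-out cross-validation over samples is the evaluation protocol.

The quadratic-programming core of the SVR and the NIPALS core of the PLS
are delegated to scikit-learn; the hyperparameter search, the kernel
convention, the fitness protocol and the cross-validation study are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR as _SkSVR

from .metrics import CalibrationReport, r_coefficient, rmsep
from .synthetic import SpectraDataset

__all__ = [
    "SVRHyper",
    "PSOConfig",
    "CalibrationModel",
    "rbf_kernel",
    "svr_train",
    "svr_predict",
    "pso_optimize",
    "pso_svr_fit",
    "pls_fit",
    "pls_predict",
    "loocv",
]

# hyperparameter search box (ε, C, γ)
EPS_BOUNDS = (0.0, 0.2)
C_BOUNDS = (1.0, 1e8)
GAMMA_BOUNDS = (0.01, 2.0)


@dataclass(frozen=True)
class SVRHyper:
    """ε-SVR hyperparameters; γ follows the exp(-d²/(2γ²)) convention."""

    epsilon: float = 0.1
    C: float = 100.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")

    @property
    def sklearn_gamma(self) -> float:
        # scikit-learn uses exp(-g d^2): g = 1/(2 γ^2)
        return 1.0 / (2.0 * self.gamma ** 2)


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings: inertia decreases linearly from omega_max to omega_min."""

    swarm_size: int = 10
    omega_max: float = 0.9
    omega_min: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    iter_max: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.omega_max < self.omega_min:
            raise ValueError("omega_max must be >= omega_min")


@dataclass
class CalibrationModel:
    """Trained regressor with enough state to predict new spectra."""

    model_kind: str                       # "SVR" | "PLS"
    hyper: SVRHyper | None = None
    dual_coef: np.ndarray | None = None   # (â - a)_i on support vectors
    support_vectors: np.ndarray | None = None
    bias: float = 0.0
    pls: PLSRegression | None = None
    n_components: int | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is not None:
            X = (X - self.x_mean) / self.x_scale
        return X


def rbf_kernel(xi, xj, gamma: float) -> float:
    """exp(-||xi-xj||^2 / (2 γ^2)) for a single pair of feature vectors."""
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if xi.size != xj.size:
        raise ValueError("feature dimensions differ")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / (2.0 * gamma ** 2)))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def svr_train(X, y, hyper: SVRHyper, standardize: bool = False) -> CalibrationModel:
    """Solve the ε-SVR dual with RBF kernel; returns the trained model.

    Features are used on their native scale by default: for absorbance
    spectra the pairwise distances are then of order one, the regime the
    γ ∈ [0.01, 2] search box assumes.  Column standardization is
    available for heterogeneous feature sets.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or X.shape[0] < 2:
        raise ValueError("need >= 2 samples with matching X rows")
    if standardize:
        Xs, mean, scale = _standardize(X)
    else:
        Xs, mean, scale = X, None, None
    sk = _SkSVR(kernel="rbf", C=hyper.C, epsilon=hyper.epsilon,
                gamma=hyper.sklearn_gamma, tol=1e-6, max_iter=2_000_000)
    sk.fit(Xs, y)
    if sk.fit_status_ != 0:
        raise RuntimeError("SVR solver did not converge")
    return CalibrationModel(
        model_kind="SVR", hyper=hyper,
        dual_coef=sk.dual_coef_.ravel().copy(),
        support_vectors=sk.support_vectors_.copy(),
        bias=float(sk.intercept_[0]),
        x_mean=mean, x_scale=scale,
    )


def svr_predict(model: CalibrationModel, X) -> np.ndarray:
    """Σ (â-a)_i K(x_i, x) + b* for each row of X."""
    if model.model_kind != "SVR":
        raise ValueError("model is not an SVR")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sv = model.support_vectors
    if X.shape[1] != sv.shape[1]:
        raise ValueError("feature dimension mismatch")
    Xs = model._transform(X)
    if sv.shape[0] == 0:
        return np.full(X.shape[0], model.bias)
    d2 = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2.0 * model.hyper.gamma ** 2))
    return K @ model.dual_coef + model.bias


@dataclass
class PSOResult:
    position: np.ndarray
    fitness: float
    trace: np.ndarray  # gbest fitness per iteration, non-increasing


def pso_optimize(fitness: Callable[[np.ndarray], float],
                 bounds: Sequence[tuple[float, float]],
                 cfg: PSOConfig | None = None) -> PSOResult:
    """Global-best PSO with linearly decreasing inertia.

    Velocity update: v <- ω v + c1 r1 (pbest - x) + c2 r2 (gbest - x),
    with ω = ω_min + (iter_max - iter)(ω_max - ω_min)/iter_max.
    Positions are clamped to the bounds (velocity zeroed in the clamped
    dimension); velocities are clamped to 20% of each bound's range.
    A particle returning a non-finite fitness is re-initialized.
    """
    cfg = cfg or PSOConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (dims, 2) array")
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    vmax = 0.2 * span
    rng = np.random.default_rng(cfg.seed)
    m, d = cfg.swarm_size, bounds.shape[0]

    x = lo + rng.random((m, d)) * span
    v = (rng.random((m, d)) - 0.5) * vmax

    def safe_eval(pos: np.ndarray) -> float:
        val = float(fitness(pos))
        return val if np.isfinite(val) else np.inf

    f = np.array([safe_eval(xi) for xi in x])
    # re-draw particles that started on non-finite fitness
    for i in np.flatnonzero(~np.isfinite(f) | (f == np.inf)):
        for _ in range(10):
            x[i] = lo + rng.random(d) * span
            f[i] = safe_eval(x[i])
            if np.isfinite(f[i]) and f[i] < np.inf:
                break
    pbest, pf = x.copy(), f.copy()
    g = int(np.argmin(pf))
    gbest, gf = pbest[g].copy(), float(pf[g])
    trace = [gf]

    for it in range(cfg.iter_max):
        omega = cfg.omega_min + (cfg.iter_max - it) * (
            cfg.omega_max - cfg.omega_min) / cfg.iter_max
        r1 = rng.random((m, d))
        r2 = rng.random((m, d))
        v = omega * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = x + v
        low, high = x < lo, x > hi
        v[low | high] = 0.0
        x = np.clip(x, lo, hi)
        f = np.array([safe_eval(xi) for xi in x])
        improved = f < pf
        pbest[improved] = x[improved]
        pf[improved] = f[improved]
        g = int(np.argmin(pf))
        if pf[g] < gf:
            gbest, gf = pbest[g].copy(), float(pf[g])
        trace.append(gf)
    return PSOResult(position=gbest, fitness=gf, trace=np.asarray(trace))


def _cv_folds(n: int, rng: np.random.Generator, k: int = 5):
    """Index folds: leave-one-out for small n, shuffled k-fold otherwise."""
    if n <= 20:
        return [np.array([i]) for i in range(n)]
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def _cv_rms(X: np.ndarray, y: np.ndarray, hyper: SVRHyper,
            folds) -> float:
    """Root-mean-square CV prediction error — the PSO fitness."""
    preds = np.empty_like(y)
    for test in folds:
        train = np.setdiff1d(np.arange(y.size), test)
        try:
            model = svr_train(X[train], y[train], hyper)
        except (RuntimeError, ValueError):
            return np.inf
        preds[test] = svr_predict(model, X[test])
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def pso_svr_fit(X, y, cfg: PSOConfig | None = None
                ) -> tuple[CalibrationModel, SVRHyper, np.ndarray]:
    """Jointly select (ε, C, γ) by PSO and retrain on all data.

    The particle encodes (ε, log10 C, γ); C spans eight decades so its
    dimension is searched in log space.  The fitness is the
    cross-validated RMS prediction error within the training data
    (leave-one-out for n ≤ 20, 5-fold otherwise).
    """
    cfg = cfg or PSOConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need >= 3 samples")
    rng = np.random.default_rng(cfg.seed + 1)
    folds = _cv_folds(y.size, rng)
    bounds = [EPS_BOUNDS,
              (np.log10(C_BOUNDS[0]), np.log10(C_BOUNDS[1])),
              GAMMA_BOUNDS]

    def fitness(pos: np.ndarray) -> float:
        hyper = SVRHyper(epsilon=float(pos[0]), C=float(10.0 ** pos[1]),
                         gamma=float(pos[2]))
        return _cv_rms(X, y, hyper, folds)

    result = pso_optimize(fitness, bounds, cfg)
    if not np.isfinite(result.fitness):
        raise RuntimeError("PSO-SVR: every candidate fit failed")
    best = SVRHyper(epsilon=float(result.position[0]),
                    C=float(10.0 ** result.position[1]),
                    gamma=float(result.position[2]))
    model = svr_train(X, y, best)
    return model, best, result.trace


def model_to_dict(model: CalibrationModel) -> dict:
    """JSON-serializable form of a trained model (SVR or PLS)."""
    if model.model_kind == "SVR":
        return {
            "model_kind": "SVR",
            "hyper": {"epsilon": model.hyper.epsilon, "C": model.hyper.C,
                      "gamma": model.hyper.gamma},
            "dual_coef": model.dual_coef.tolist(),
            "support_vectors": model.support_vectors.tolist(),
            "bias": model.bias,
            "x_mean": None if model.x_mean is None else model.x_mean.tolist(),
            "x_scale": None if model.x_scale is None else model.x_scale.tolist(),
        }
    if model.model_kind == "PLS":
        return {
            "model_kind": "PLS",
            "n_components": model.n_components,
            "coef": model.pls.coef_.ravel().tolist(),
            "intercept": float(np.ravel(model.pls.intercept_)[0]),
            "x_mean": model.pls._x_mean.tolist(),
        }
    raise ValueError(f"unknown model kind {model.model_kind!r}")


class _StoredPLS:
    """Prediction-only stand-in reconstructed from serialized coefficients."""

    def __init__(self, coef: np.ndarray, intercept: float, x_mean: np.ndarray):
        self.coef_ = coef.reshape(1, -1)
        self.intercept_ = np.array([intercept])
        self._x_mean = x_mean

    def predict(self, X):
        return (X - self._x_mean) @ self.coef_.ravel() + self.intercept_[0]


def model_from_dict(d: dict) -> CalibrationModel:
    """Rebuild a prediction-capable model from :func:`model_to_dict` output."""
    kind = d["model_kind"]
    if kind == "SVR":
        return CalibrationModel(
            model_kind="SVR",
            hyper=SVRHyper(**d["hyper"]),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            bias=float(d["bias"]),
            x_mean=None if d["x_mean"] is None else np.asarray(d["x_mean"]),
            x_scale=None if d["x_scale"] is None else np.asarray(d["x_scale"]),
        )
    if kind == "PLS":
        stored = _StoredPLS(np.asarray(d["coef"], dtype=float),
                            float(d["intercept"]),
                            np.asarray(d["x_mean"], dtype=float))
        return CalibrationModel(model_kind="PLS", pls=stored,
                                n_components=int(d["n_components"]))
    raise ValueError(f"unknown model kind {kind!r}")


def pls_fit(X, y, n_components: int) -> CalibrationModel:
    """Centered PLS1 regression (NIPALS) with ``n_components`` latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        import warnings
        warnings.warn(f"n_components reduced from {n_components} to {max_comp}")
        n_components = max_comp
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return CalibrationModel(model_kind="PLS", pls=pls, n_components=n_components)


def pls_predict(model: CalibrationModel, X) -> np.ndarray:
    if model.model_kind != "PLS":
        raise ValueError("model is not a PLS")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.pls.predict(X).ravel()


def select_pls_components(X, y, max_components: int = 10) -> int:
    """Pick the PLS component count minimizing leave-one-out RMSEP."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    cap = min(max_components, n - 2, X.shape[1])
    best_k, best_err = 1, np.inf
    for k in range(1, cap + 1):
        preds = np.empty(n)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            m = pls_fit(X[tr], y[tr], k)
            preds[i] = pls_predict(m, X[i:i + 1])[0]
        err = float(np.sqrt(np.mean((preds - y) ** 2)))
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def loocv(dataset: SpectraDataset,
          fit_fn: Callable[[np.ndarray, np.ndarray], object],
          predict_fn: Callable[[object, np.ndarray], np.ndarray]
          ) -> CalibrationReport:
    """Leave-one-out cross-validation over samples.

    ``fit_fn(X_train, y_train)`` returns a model; ``predict_fn(model,
    X_test)`` returns predictions.  A failing fold contributes NaN and
    is excluded from the aggregate metrics.
    """
    X = dataset.absorbance
    y = dataset.concentrations
    n = dataset.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples for LOOCV")
    preds = np.full(n, np.nan)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        try:
            model = fit_fn(X[tr], y[tr])
            preds[i] = float(np.asarray(predict_fn(model, X[i:i + 1])).ravel()[0])
        except Exception:
            pass
    ok = np.isfinite(preds)
    if ok.sum() < 2:
        raise RuntimeError("too few successful LOOCV folds")
    return CalibrationReport(
        r=r_coefficient(y[ok], preds[ok]),
        rmsep=rmsep(y[ok], preds[ok]),
        predictions=preds, truth=y.copy(),
    )
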