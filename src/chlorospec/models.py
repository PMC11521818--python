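"""Regression model families for chlorophyll estimation.

Six presets, each fixed to the hyper-parameter set used in the study design:

=================  =========================================================
robust_linear      Linear terms, Huber loss fitted by IRLS (robust option on)
stepwise_linear    Initial terms linear, candidate pairwise interactions,
                   partial-F stepwise selection, at most 1000 steps
svm_quadratic      eps-SVR, quadratic polynomial kernel, automatic kernel
                   scale / box constraint / epsilon, standardized features
svm_fine_gaussian  eps-SVR, Gaussian kernel with kernel scale 0.83,
                   automatic box constraint / epsilon, standardized features
gpr_matern52       Exact GP regression, constant basis, isotropic Matern 5/2
                   kernel, Gaussian noise, hyper-parameters optimized by
                   marginal likelihood, standardized features
trilayer_nn        Fully connected net, three hidden layers of 20 ReLU
                   units, linear output, L2 strength 0, iteration limit
                   1000, full-batch quasi-Newton training, standardized data
=================  =========================================================

"Automatic" support-vector settings follow the convention of the
interactive toolboxes this family of models is usually fitted with: the box
constraint is ``iqr(y) / 1.349`` (a robust estimate of the response scale)
and the epsilon tube is a tenth of that.

The loss and kernel primitives are exposed directly:

    huber_loss(r, delta)     = r^2/2                 for |r| <= delta
                               delta*(|r| - delta/2) otherwise
    kernel_gaussian(x, y)    = exp(-||x-y||^2 / (2 sigma^2))
    kernel_matern52(r)       = sigma * (1 + sqrt5 r/l + 5 r^2/(3 l^2))
                               * exp(-sqrt5 r/l)

``sigma`` in the Matern kernel is the variance-scale parameter, i.e. the
kernel's value at r = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.random import default_rng
from scipy.stats import f as f_dist
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import ConfigurationError, DecompositionError, DomainError, InputError

__all__ = [
    "PRESETS",
    "ModelSpec",
    "HuberConfig",
    "GaussianKernelParams",
    "MaternParams",
    "FittedModel",
    "huber_loss",
    "kernel_gaussian",
    "kernel_matern52",
    "fit_robust_linear",
    "fit_stepwise",
    "fit_svr",
    "fit_gpr",
    "fit_trilayer_nn",
    "fit_model",
    "predict",
]

PRESETS = (
    "robust_linear",
    "stepwise_linear",
    "svm_quadratic",
    "svm_fine_gaussian",
    "gpr_matern52",
    "trilayer_nn",
)

FINE_GAUSSIAN_KERNEL_SCALE = 0.83


@dataclass(frozen=True)
class ModelSpec:
    """A model preset plus overridable hyper-parameters."""

    preset: str
    hyperparams: dict = field(default_factory=dict)
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ConfigurationError(f"unknown preset {self.preset!r}; choose from {PRESETS}")


@dataclass(frozen=True)
class HuberConfig:
    """IRLS settings for the robust linear fit.

    ``delta=None`` uses the conventional 1.345 x robust residual scale
    (median-absolute-deviation based), re-estimated every iteration; an
    explicit delta is an absolute residual threshold in response units.
    """

    delta: float | None = None
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta <= 0:
            raise DomainError("delta must be > 0")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class GaussianKernelParams:
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError("sigma must be > 0")


@dataclass(frozen=True)
class MaternParams:
    sigma: float = 1.0
    length_scale: float = 1.0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.length_scale <= 0:
            raise DomainError("sigma and length_scale must be > 0")
        if self.jitter < 0:
            raise DomainError("jitter must be >= 0")


@dataclass
class FittedModel:
    """A trained model: spec, learned state and a deterministic predictor."""

    spec: ModelSpec
    state: dict
    training_summary: dict
    _predictor: Callable[[np.ndarray], np.ndarray]
    n_features: int
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


# ---------------------------------------------------------------------------
# primitives


def huber_loss(residual, delta: float):
    """Huber loss: quadratic inside |r| <= delta, linear outside.

    Continuous and once-differentiable at the knot; vectorized over r.
    """
    if delta <= 0:
        raise DomainError("delta must be > 0")
    r = np.abs(np.asarray(residual, dtype=float))
    out = np.where(r <= delta, 0.5 * r**2, delta * (r - 0.5 * delta))
    return float(out) if out.ndim == 0 else out


def kernel_gaussian(x: np.ndarray, y: np.ndarray, params: GaussianKernelParams) -> float:
    """Gaussian (RBF) similarity exp(-||x-y||^2 / (2 sigma^2)), in (0, 1]."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise InputError("x and y must have equal dimension")
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * params.sigma**2)))


def kernel_matern52(r, params: MaternParams):
    """Matern 5/2 covariance at distance r >= 0; equals sigma at r = 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise DomainError("distance r must be >= 0")
    u = np.sqrt(5.0) * r / params.length_scale
    out = params.sigma * (1.0 + u + u**2 / 3.0) * np.exp(-u)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# shared helpers


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise InputError("X and y length mismatch")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise InputError("non-finite values in X or y")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _apply_standardization(model: FittedModel, X: np.ndarray) -> np.ndarray:
    if model.x_mean is None:
        return X
    return (X - model.x_mean) / model.x_scale


def _auto_box_epsilon(y: np.ndarray) -> tuple[float, float]:
    iqr = float(np.subtract(*np.percentile(y, [75, 25])))
    box = iqr / 1.349 if iqr > 0 else 1.0
    return box, box / 10.0


# ---------------------------------------------------------------------------
# robust linear (Huber IRLS)


def fit_robust_linear(X, y, config: HuberConfig | None = None) -> FittedModel:
    """Huber-loss linear regression by iteratively reweighted least squares.

    With a delta far above the residual scale every weight is 1 and the fit
    coincides with ordinary least squares; a heavy outlier is down-weighted
    by ``delta / |r|``.
    """
    config = config or HuberConfig()
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n <= p + 1:
        raise InputError("need n > number of coefficients")
    design = np.column_stack([np.ones(n), X])

    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise DecompositionError("singular design matrix")

    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        resid = y - design @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6745 if mad > 0 else 0.0
        delta = config.delta if config.delta is not None else 1.345 * scale
        if delta <= 0:  # perfect fit: residuals all (numerically) zero
            converged = True
            break
        a = np.abs(resid)
        w = np.where(a <= delta, 1.0, delta / np.where(a > 0, a, 1.0))
        sw = np.sqrt(w)
        new_beta, _, _, _ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        change = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if change < config.tolerance:
            converged = True
            break

    coef = beta.copy()
    return FittedModel(
        spec=ModelSpec("robust_linear"),
        state={"intercept": float(coef[0]), "coefficients": coef[1:].tolist()},
        training_summary={"iterations": iterations, "converged": converged},
        _predictor=lambda Z: np.column_stack([np.ones(Z.shape[0]), Z]) @ coef,
        n_features=p,
    )


# ---------------------------------------------------------------------------
# stepwise linear with interactions


def _term_matrix(X: np.ndarray, names: list[str], interactions: bool):
    cols = [X[:, j] for j in range(X.shape[1])]
    labels = list(names)
    if interactions:
        for i in range(X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                cols.append(X[:, i] * X[:, j])
                labels.append(f"{names[i]}*{names[j]}")
    return np.column_stack(cols), labels


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ coef
    return float((r**2).sum())


def _partial_f_pvalue(rss_small: float, rss_big: float, df_resid_big: int) -> float:
    if df_resid_big <= 0 or rss_big <= 0:
        return 0.0
    fstat = (rss_small - rss_big) / (rss_big / df_resid_big)
    if fstat <= 0:
        return 1.0
    return float(f_dist.sf(fstat, 1, df_resid_big))


def fit_stepwise(
    X,
    y,
    feature_names: list[str] | None = None,
    direction: str = "bidirectional",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 1000,
    include_interactions: bool = True,
) -> FittedModel:
    """Stepwise term selection over linear terms and pairwise interactions.

    Entry/removal is decided by partial-F p-values.  Forward selection
    starts from the empty (intercept-only) model; backward and bidirectional
    start from all linear terms (the interaction terms are the upper bound
    on model complexity).  ``max_steps=0`` returns the initial model as is.
    """
    if direction not in ("forward", "backward", "bidirectional"):
        raise ConfigurationError("direction must be forward, backward or bidirectional")
    if p_enter > p_remove:
        raise ConfigurationError("p_enter must not exceed p_remove")
    X, y = _as_xy(X, y)
    n, p = X.shape
    names = feature_names or [f"x{j + 1}" for j in range(p)]
    if len(names) != p:
        raise InputError("feature_names length mismatch")
    terms, labels = _term_matrix(X, names, include_interactions)

    n_linear = p
    current = list(range(n_linear)) if direction != "forward" else []
    if direction != "forward" and n <= n_linear + 1:
        raise InputError("need n > linear term count for a backward start")

    def design_for(idx: list[int]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [terms[:, i] for i in idx])

    steps = 0
    while steps < max_steps:
        changed = False
        rss_cur = _rss(design_for(current), y)
        df_cur = n - len(current) - 1

        if direction in ("backward", "bidirectional") and current:
            worst, worst_p = -1, -1.0
            for t in current:
                rest = [i for i in current if i != t]
                p_val = _partial_f_pvalue(_rss(design_for(rest), y), rss_cur, df_cur)
                if p_val > worst_p:
                    worst, worst_p = t, p_val
            if worst_p > p_remove:
                current.remove(worst)
                steps += 1
                changed = True

        if not changed and direction in ("forward", "bidirectional"):
            candidates = [i for i in range(terms.shape[1]) if i not in current]
            best, best_p = -1, 2.0
            for t in candidates:
                df_new = n - len(current) - 2
                if df_new <= 0:
                    continue
                p_val = _partial_f_pvalue(rss_cur, _rss(design_for(current + [t]), y), df_new)
                if p_val < best_p:
                    best, best_p = t, p_val
            if best >= 0 and best_p < p_enter:
                current.append(best)
                steps += 1
                changed = True

        if not changed:
            break

    idx = list(current)
    design = design_for(idx)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    term_cols = terms[:, idx] if idx else np.empty((n, 0))

    def predictor(Z: np.ndarray) -> np.ndarray:
        tz, _ = _term_matrix(Z, names, include_interactions)
        d = np.column_stack([np.ones(Z.shape[0])] + [tz[:, i] for i in idx])
        return d @ coef

    return FittedModel(
        spec=ModelSpec("stepwise_linear"),
        state={
            "selected_terms": [labels[i] for i in idx],
            "intercept": float(coef[0]),
            "coefficients": coef[1:].tolist(),
        },
        training_summary={
            "steps": steps,
            "converged": steps < max_steps,
            "selected_terms": [labels[i] for i in idx],
            "n_candidate_terms": terms.shape[1],
        },
        _predictor=predictor,
        n_features=p,
    )


# ---------------------------------------------------------------------------
# support-vector regression


def fit_svr(X, y, spec: ModelSpec) -> FittedModel:
    """eps-insensitive SVR with a quadratic-polynomial or Gaussian kernel."""
    if spec.preset not in ("svm_quadratic", "svm_fine_gaussian"):
        raise ConfigurationError("fit_svr expects an SVM preset")
    X, y = _as_xy(X, y)
    if X.shape[0] < 2:
        raise InputError("need at least 2 samples")

    Xs, mean, scale = _standardize(X) if spec.standardize else (X, None, None)
    box = spec.hyperparams.get("box_constraint")
    eps = spec.hyperparams.get("epsilon")
    auto_box, auto_eps = _auto_box_epsilon(y)
    box = auto_box if box is None else box
    eps = auto_eps if eps is None else eps

    if spec.preset == "svm_quadratic":
        model = SVR(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=box, epsilon=eps)
        kernel_scale = "auto"
    else:
        ks = spec.hyperparams.get("kernel_scale", FINE_GAUSSIAN_KERNEL_SCALE)
        model = SVR(kernel="rbf", gamma=1.0 / (2.0 * ks**2), C=box, epsilon=eps)
        kernel_scale = ks
    model.fit(Xs, y)

    return FittedModel(
        spec=spec,
        state={
            "kernel_scale": kernel_scale,
            "box_constraint": box,
            "epsilon": eps,
            "n_support": int(model.n_support_.sum()) if hasattr(model, "n_support_") else len(model.support_),
        },
        training_summary={"n_support_vectors": len(model.support_)},
        _predictor=model.predict,
        n_features=X.shape[1],
        x_mean=mean,
        x_scale=scale,
    )


# ---------------------------------------------------------------------------
# Gaussian process regression, Matern 5/2


def fit_gpr(X, y, spec: ModelSpec | None = None) -> FittedModel:
    """Exact GPR: constant basis, isotropic Matern 5/2, Gaussian noise.

    Kernel variance, length scale and noise variance are optimized by
    maximizing the log marginal likelihood (quasi-Newton on log-parameters,
    with restarts).  Set ``hyperparams={"noise": "zero"}`` to pin the noise
    variance to zero (jitter only), which makes the posterior mean
    interpolate the training data.
    """
    spec = spec or ModelSpec("gpr_matern52")
    if spec.preset != "gpr_matern52":
        raise ConfigurationError("fit_gpr expects the gpr_matern52 preset")
    X, y = _as_xy(X, y)
    if X.shape[0] < 2:
        raise InputError("need at least 2 samples")

    Xs, mean, scale = _standardize(X) if spec.standardize else (X, None, None)
    noise_mode = spec.hyperparams.get("noise", "optimize")
    restarts = int(spec.hyperparams.get("n_restarts", 2))

    base = ConstantKernel(1.0, (1e-4, 1e6)) * Matern(length_scale=1.0, length_scale_bounds=(1e-3, 1e4), nu=2.5)
    if noise_mode == "zero":
        kernel = base
        alpha = 1e-10
    else:
        kernel = base + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-12, 1e2))
        alpha = 1e-10

    for jitter in (alpha, 1e-8, 1e-6):
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=jitter,
            normalize_y=True,
            n_restarts_optimizer=restarts,
            random_state=spec.seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(Xs, y)
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise DecompositionError("Cholesky failed after jitter escalation")

    def predictor(Z: np.ndarray, return_std: bool = False):
        return gp.predict(Z, return_std=return_std)

    return FittedModel(
        spec=spec,
        state={
            "kernel": str(gp.kernel_),
            "log_marginal_likelihood": float(gp.log_marginal_likelihood_value_),
            "constant_mean": float(gp._y_train_mean[0]) if np.ndim(gp._y_train_mean) else float(gp._y_train_mean),
        },
        training_summary={"optimized": True, "noise": noise_mode},
        _predictor=predictor,
        n_features=X.shape[1],
        x_mean=mean,
        x_scale=scale,
    )


def predict_with_std(model: FittedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """GPR predictive mean and standard deviation."""
    if model.spec.preset != "gpr_matern52":
        raise ConfigurationError("predictive variance is only available for GPR")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise InputError("feature count mismatch")
    return model._predictor(_apply_standardization(model, X), return_std=True)


# ---------------------------------------------------------------------------
# trilayered neural network


def fit_trilayer_nn(X, y, spec: ModelSpec | None = None) -> FittedModel:
    """Three hidden layers of 20 ReLU units, linear output, L2 = 0.

    Trained full batch with a quasi-Newton optimizer so that, for a fixed
    seed, weights and predictions are bit-reproducible; both features and
    the response are standardized internally for conditioning (the response
    scaling is inverted at prediction time).
    """
    spec = spec or ModelSpec("trilayer_nn")
    if spec.preset != "trilayer_nn":
        raise ConfigurationError("fit_trilayer_nn expects the trilayer_nn preset")
    X, y = _as_xy(X, y)
    if X.shape[0] < 10:
        raise InputError("need at least 10 samples")

    layer = int(spec.hyperparams.get("layer_size", 20))
    max_iter = int(spec.hyperparams.get("iteration_limit", 1000))
    lam = float(spec.hyperparams.get("lambda", 0.0))

    Xs, mean, scale = _standardize(X) if spec.standardize else (X, None, None)
    y_mean, y_scale = y.mean(), y.std() if y.std() > 0 else 1.0
    ys = (y - y_mean) / y_scale

    net = MLPRegressor(
        hidden_layer_sizes=(layer, layer, layer),
        activation="relu",
        solver="lbfgs",
        alpha=lam,
        max_iter=max_iter,
        max_fun=10 * max(1, max_iter),
        tol=1e-10,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Xs, ys)

    return FittedModel(
        spec=spec,
        state={"layers": (layer, layer, layer), "lambda": lam},
        training_summary={"iterations": int(net.n_iter_), "converged": int(net.n_iter_) < max_iter},
        _predictor=lambda Z: net.predict(Z) * y_scale + y_mean,
        n_features=X.shape[1],
        x_mean=mean,
        x_scale=scale,
    )


# ---------------------------------------------------------------------------
# dispatch and prediction


def fit_model(X, y, spec: ModelSpec) -> FittedModel:
    """Fit any preset from a ModelSpec."""
    if spec.preset == "robust_linear":
        return fit_robust_linear(X, y, spec.hyperparams.get("huber", HuberConfig()))
    if spec.preset == "stepwise_linear":
        hp = spec.hyperparams
        return fit_stepwise(
            X,
            y,
            feature_names=hp.get("feature_names"),
            direction=hp.get("direction", "bidirectional"),
            p_enter=hp.get("p_enter", 0.05),
            p_remove=hp.get("p_remove", 0.10),
            max_steps=hp.get("max_steps", 1000),
        )
    if spec.preset in ("svm_quadratic", "svm_fine_gaussian"):
        return fit_svr(X, y, spec)
    if spec.preset == "gpr_matern52":
        return fit_gpr(X, y, spec)
    if spec.preset == "trilayer_nn":
        return fit_trilayer_nn(X, y, spec)
    raise ConfigurationError(f"unknown preset {spec.preset!r}")


def predict(model: FittedModel, X) -> np.ndarray:
    """Deterministic prediction, applying the stored standardization."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise InputError(
            f"feature count mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    out = model._predictor(_apply_standardization(model, X))
    return np.asarray(out, dtype=float).ravel()
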