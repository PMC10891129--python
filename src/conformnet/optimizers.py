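"""From-scratch SGD, RMSprop and Adam fits of the line H(x) = θ0 + θ1·x.

The objective is mean squared error

    Q(θ0, θ1) = (1/m) Σ_i (θ0 + θ1 x_i − y_i)²,

minimised by three optimizers sharing one protocol: parameters start
from U(0,1), each epoch is one shuffled pass over the data (per-example
updates for SGD, mini-batches for RMSprop and Adam), and the run stops
when the full-data gradient norm drops to ``grad_tol`` or the epoch
budget runs out.

Adam's moment rescaling is offered in two modes. ``paper_literal``
divides the accumulators by the constants (1−β1) and (1−β2);
``time_scaled`` divides by (1−β1^t) and (1−β2^t) as in the standard
formulation. The modes coincide on the first step and differ only by a
bounded rescaling afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernels
from .synthetic_data import RegressionDataset

__all__ = [
    "LinearModelParams",
    "OptimizerConfig",
    "FitResult",
    "DivergenceError",
    "objective_and_gradient",
    "fit_sgd",
    "fit_rmsprop",
    "fit_adam",
    "fit",
    "predict",
    "least_squares_fit",
    "default_config",
]

Method = Literal["SGD", "RMSPROP", "ADAM"]


class DivergenceError(RuntimeError):
    """Raised when a fit produces non-finite parameters."""

    def __init__(self, method: str, epoch: int):
        super().__init__(f"{method} diverged to non-finite parameters at epoch {epoch}")
        self.method = method
        self.epoch = epoch


@dataclass(frozen=True)
class LinearModelParams:
    theta0: float
    theta1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta0) and np.isfinite(self.theta1)):
            raise ValueError("model parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta0, self.theta1])


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters for one optimizer run.

    Defaults follow the simulation protocol: learning rate η=0.001, at
    most 3000 epochs, gradient tolerance 0.001; RMSprop uses β=0.9,
    ε=1e−6 and batch size 16; Adam uses β1=0.9, β2=0.999, ε=1e−8 and
    the same batch size.
    """

    method: Method = "SGD"
    eta: float = 1e-3
    max_iters: int = 3000
    grad_tol: float = 1e-3
    batch_size: int = 16
    beta: float = 0.9          # RMSprop decay
    beta1: float = 0.9         # Adam first-moment decay
    beta2: float = 0.999       # Adam second-moment decay
    eps: float = 1e-6          # RMSprop guard; Adam overrides via adam_eps
    adam_eps: float = 1e-8
    bias_correction: Literal["paper_literal", "time_scaled"] = "paper_literal"
    init_seed: int = 0
    shuffle_seed: int = 1

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        for name in ("beta", "beta1", "beta2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.eps <= 0 or self.adam_eps <= 0:
            raise ValueError("eps must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


def default_config(method: Method, init_seed: int = 0, shuffle_seed: int = 1) -> OptimizerConfig:
    return OptimizerConfig(method=method, init_seed=init_seed, shuffle_seed=shuffle_seed)


@dataclass(frozen=True)
class FitResult:
    params: LinearModelParams
    predictions: np.ndarray
    epochs_run: int
    final_grad_norm: float
    converged: bool
    objective_trace: np.ndarray

    def trace_frame(self) -> pd.DataFrame:
        """Objective trace as a flat table, one row per epoch, plus a summary row."""
        rows = pd.DataFrame(
            {"epoch": np.arange(1, len(self.objective_trace) + 1), "Q": self.objective_trace}
        )
        summary = pd.DataFrame(
            {
                "epoch": ["final"],
                "Q": [np.nan],
                "theta0": [self.params.theta0],
                "theta1": [self.params.theta1],
                "grad_norm": [self.final_grad_norm],
                "converged": [self.converged],
            }
        )
        return pd.concat([rows, summary], ignore_index=True)


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, RegressionDataset):
        x, y = dataset.x, dataset.y
    else:
        x, y = dataset
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("dataset must provide equal-length, nonempty x and y")
    return x, y


def objective_and_gradient(params: LinearModelParams, dataset) -> tuple[float, tuple[float, float]]:
    """Mean-squared-error objective Q and its gradient in (θ0, θ1)."""
    x, y = _as_xy(dataset)
    r = params.theta0 + params.theta1 * x - y
    q = float(np.mean(r**2))
    g0 = float(2.0 * np.mean(r))
    g1 = float(2.0 * np.mean(r * x))
    return q, (g0, g1)


def predict(params: LinearModelParams, x) -> np.ndarray:
    return params.theta0 + params.theta1 * np.asarray(x, dtype=float)


def least_squares_fit(dataset) -> LinearModelParams:
    """Closed-form least-squares line, the reference optimum for all fits."""
    x, y = _as_xy(dataset)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearModelParams(theta0=float(coef[0]), theta1=float(coef[1]))


def _init_theta(config: OptimizerConfig, theta_init) -> tuple[float, float]:
    if theta_init is not None:
        return float(theta_init[0]), float(theta_init[1])
    rng = np.random.default_rng(config.init_seed)
    t0, t1 = rng.uniform(size=2)
    return float(t0), float(t1)


def _permutations(config: OptimizerConfig, m: int) -> np.ndarray:
    rng = np.random.default_rng(config.shuffle_seed)
    perms = np.empty((config.max_iters, m), dtype=np.int64)
    for e in range(config.max_iters):
        perms[e] = rng.permutation(m)
    return perms


def _finish(method, x, t0, t1, epochs, gnorm, status, trace, grad_tol) -> FitResult:
    if status != 0:
        raise DivergenceError(method, epochs)
    params = LinearModelParams(theta0=t0, theta1=t1)
    return FitResult(
        params=params,
        predictions=predict(params, x),
        epochs_run=int(epochs),
        final_grad_norm=float(gnorm),
        converged=bool(gnorm <= grad_tol),
        objective_trace=np.asarray(trace, dtype=float),
    )


def fit_sgd(dataset, config: OptimizerConfig | None = None, theta_init=None) -> FitResult:
    """Per-example stochastic gradient descent.

    Each epoch shuffles the data and loops over the m examples, updating
    both parameters simultaneously from the start-of-step θ:

        θ0 ← θ0 − η · 2(θ0 + θ1 x_i − y_i)
        θ1 ← θ1 − η · 2 x_i (θ0 + θ1 x_i − y_i)
    """
    config = config or default_config("SGD")
    if config.method != "SGD":
        raise ValueError(f"fit_sgd requires method='SGD', got {config.method!r}")
    x, y = _as_xy(dataset)
    t0, t1 = _init_theta(config, theta_init)
    out = _kernels.sgd_kernel(x, y, t0, t1, config.eta, config.grad_tol, _permutations(config, len(x)))
    return _finish("SGD", x, *out, config.grad_tol)


def fit_rmsprop(dataset, config: OptimizerConfig | None = None, theta_init=None) -> FitResult:
    """Mini-batch RMSprop: v ← βv + (1−β)g², θ ← θ − η·g/√(v+ε)."""
    config = config or default_config("RMSPROP")
    if config.method != "RMSPROP":
        raise ValueError(f"fit_rmsprop requires method='RMSPROP', got {config.method!r}")
    x, y = _as_xy(dataset)
    t0, t1 = _init_theta(config, theta_init)
    out = _kernels.rmsprop_kernel(
        x, y, t0, t1, config.eta, config.beta, config.eps, config.batch_size,
        config.grad_tol, _permutations(config, len(x)),
    )
    return _finish("RMSPROP", x, *out, config.grad_tol)


def fit_adam(dataset, config: OptimizerConfig | None = None, theta_init=None) -> FitResult:
    """Mini-batch Adam with first/second-moment accumulators.

    The rescaled moments m̂, v̂ divide by constants (1−β1), (1−β2) in
    ``paper_literal`` mode or by (1−β1^t), (1−β2^t) in ``time_scaled``
    mode; the update is θ ← θ − η·m̂/(√v̂ + ε).
    """
    config = config or default_config("ADAM")
    if config.method != "ADAM":
        raise ValueError(f"fit_adam requires method='ADAM', got {config.method!r}")
    x, y = _as_xy(dataset)
    t0, t1 = _init_theta(config, theta_init)
    out = _kernels.adam_kernel(
        x, y, t0, t1, config.eta, config.beta1, config.beta2, config.adam_eps,
        config.batch_size, config.grad_tol, _permutations(config, len(x)),
        config.bias_correction == "time_scaled",
    )
    return _finish("ADAM", x, *out, config.grad_tol)


_FITTERS = {"SGD": fit_sgd, "RMSPROP": fit_rmsprop, "ADAM": fit_adam}


def fit(dataset, config: OptimizerConfig, theta_init=None) -> FitResult:
    """Dispatch to the fitter named by ``config.method``."""
    return _FITTERS[config.method](dataset, config, theta_init)
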