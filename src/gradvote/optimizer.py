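"""Gradient-descent optimization of soft-voting ensemble weights.

The ensemble prediction for instance j is the weighted sum
``sum_i w_i * p_ij`` of the base models' positive-class probabilities,
clipped to [0, 1] (weights are unconstrained reals after the first step,
so raw sums can leave the unit interval). Weights start either uniform
(1/n) or random-normalized to sum 1, and are updated by plain gradient
descent with patience-based early stopping on the validation loss; the
weights at the best validation iteration are what the fit returns.

Two loss/gradient pairings are exposed:

* ``gradient="surrogate"`` (default): the update direction is
  ``(1/N) * P @ (y_hat - y)`` — the exact gradient of the mean
  squared-error surrogate ``(1/2N) * sum (y_hat_j - y_j)^2``. The
  epsilon-stabilized binary cross-entropy is still the quantity monitored
  for early stopping.
* ``gradient="bce"``: the exact gradient of the monitored BCE itself,
  with a zero subgradient wherever clipping is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightOptimizerConfig",
    "OptimizationTrace",
    "init_weights",
    "ensemble_predict",
    "bce_loss",
    "surrogate_loss",
    "loss_gradient",
    "optimize_weights",
]

EPSILON = 1e-10


@dataclass
class WeightOptimizerConfig:
    """Hyperparameters of the weight-descent loop."""

    learning_rate: float = 0.01
    num_iterations: int = 1000
    patience: int = 10
    weight_init: str = "random"  # or "uniform"
    epsilon: float = EPSILON
    seed: int = 0
    gradient: str = "surrogate"  # or "bce"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.num_iterations < 0:
            raise ValueError("num_iterations must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.weight_init not in ("random", "uniform"):
            raise ValueError(
                f"unknown weight initializer {self.weight_init!r}; "
                "use 'random' or 'uniform'"
            )
        if self.gradient not in ("surrogate", "bce"):
            raise ValueError(f"unknown gradient mode {self.gradient!r}")


@dataclass
class OptimizationTrace:
    """Per-iteration record of one weight-descent run."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_loss: float | None = None
    best_iteration: int | None = None
    stop_reason: str = "max_iterations"

    @property
    def iterations_run(self) -> int:
        return len(self.val_losses)


def init_weights(n: int, mode: str = "random", seed: int = 0) -> np.ndarray:
    """Initial weight vector: uniform 1/n, or random draws normalized to sum 1."""
    if n < 1:
        raise ValueError("need at least one base model")
    if mode == "uniform":
        return np.ones(n) / n
    if mode == "random":
        rng = np.random.default_rng(seed)
        w = rng.random(n)  # uniform [0,1)
        return w / w.sum()
    raise ValueError(f"unknown weight initializer {mode!r}; use 'random' or 'uniform'")


def ensemble_predict(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted sum of per-model probabilities, clipped to [0, 1].

    ``P`` is n_models x n_instances; ``w`` has one weight per model.
    """
    P = np.asarray(P, dtype=float)
    w = np.asarray(w, dtype=float)
    if P.ndim != 2 or w.shape != (P.shape[0],):
        raise ValueError(
            f"dimension mismatch: P has shape {P.shape}, weights {w.shape}"
        )
    return np.clip(w @ P, 0.0, 1.0)


def bce_loss(y_true, y_pred, epsilon: float = EPSILON) -> float:
    """Mean epsilon-stabilized binary cross-entropy.

    ``-(1/N) * sum[y log(p + eps) + (1-y) log(1 - p + eps)]``; epsilon
    keeps the logarithms finite when a prediction saturates at 0 or 1.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    terms = y * np.log(p + epsilon) + (1.0 - y) * np.log(1.0 - p + epsilon)
    return float(-np.mean(terms))


def surrogate_loss(y_true, y_pred) -> float:
    """Mean squared-error surrogate ``(1/2N) * sum (p_j - y_j)^2``."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    return float(0.5 * np.mean((p - y) ** 2))


def loss_gradient(
    y_true,
    y_ens,
    P: np.ndarray,
    mode: str = "surrogate",
    epsilon: float = EPSILON,
    raw: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of the training objective with respect to the weights.

    ``surrogate``: component i is ``(1/N) * sum_j (y_hat_j - y_j) * p_ij``.
    ``bce``: chain rule through the stabilized BCE, with zero contribution
    from instances where the clip is active (``raw`` carries the
    pre-clip sums; defaults to ``y_ens`` when omitted).
    """
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_ens, dtype=float)
    P = np.asarray(P, dtype=float)
    if P.shape[1] != y.shape[0] or yh.shape != y.shape:
        raise ValueError(
            f"dimension mismatch: P {P.shape}, y {y.shape}, y_ens {yh.shape}"
        )
    n = y.shape[0]
    if mode == "surrogate":
        return (P @ (yh - y)) / n
    if mode == "bce":
        dldp = -(y / (yh + epsilon)) + (1.0 - y) / (1.0 - yh + epsilon)
        if raw is not None:
            active = (np.asarray(raw) >= 0.0) & (np.asarray(raw) <= 1.0)
            dldp = dldp * active
        return (P @ dldp) / n
    raise ValueError(f"unknown gradient mode {mode!r}")


def optimize_weights(
    P_train: np.ndarray,
    y_train,
    P_val: np.ndarray,
    y_val,
    config: WeightOptimizerConfig | None = None,
) -> tuple[np.ndarray, OptimizationTrace]:
    """Fit ensemble weights by gradient descent with early stopping.

    Each iteration aggregates the current weights, records train and
    validation BCE, updates the early-stopping bookkeeping (best loss,
    best weights, counter reset on strict improvement), stops when the
    counter reaches ``patience``, and otherwise takes one descent step
    ``w <- w - alpha * grad``. Weights are never re-normalized, so the
    fitted vector need not lie on the simplex. Returns the weights
    recorded at the best validation iteration together with the full
    trace.
    """
    config = config or WeightOptimizerConfig()
    P_train = np.asarray(P_train, dtype=float)
    P_val = np.asarray(P_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if P_train.shape[0] != P_val.shape[0]:
        raise ValueError("train and validation matrices disagree on model count")

    n_models = P_train.shape[0]
    w = init_weights(n_models, config.weight_init, config.seed)
    trace = OptimizationTrace()
    best_loss = np.inf
    best_w = w.copy()
    best_iter: int | None = None
    count = 0

    for t in range(config.num_iterations):
        raw_train = w @ P_train
        yh_train = np.clip(raw_train, 0.0, 1.0)
        yh_val = ensemble_predict(P_val, w)
        trace.train_losses.append(bce_loss(y_train, yh_train, config.epsilon))
        trace.val_losses.append(bce_loss(y_val, yh_val, config.epsilon))

        if trace.val_losses[-1] < best_loss:
            best_loss = trace.val_losses[-1]
            best_w = w.copy()
            best_iter = t
            count = 0
        else:
            count += 1
        if count >= config.patience:
            trace.stop_reason = "patience_exhausted"
            break

        grad = loss_gradient(
            y_train, yh_train, P_train,
            mode=config.gradient, epsilon=config.epsilon, raw=raw_train,
        )
        w = w - config.learning_rate * grad

    if trace.val_losses:
        trace.best_loss = best_loss
        trace.best_iteration = best_iter
    return best_w, trace
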