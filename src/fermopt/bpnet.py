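"""Single-hidden-layer feedforward surrogate for flavone yield.

The surrogate is a classic back-propagation regression network: nine inputs
(the scaled medium-component concentrations), one hidden layer of tanh
units (default 11, selectable between 3 and 13 by cross-validation), and a
single *linear* output neuron producing the scaled yield estimate.  The
linear output is essential: a bounded output unit could never predict above
the training-set maximum, while the whole point of the optimizer is to
propose media expected to outperform every training run.

Two trainers are provided, selected by :class:`TrainConfig`:

* ``levenberg_marquardt`` (default) — damped Gauss-Newton on the residual
  vector.  A trial step solves ``(JᵀJ + λI) δ = -Jᵀr``; the step is
  accepted only if the training MSE decreases, in which case λ shrinks by
  ``lm_factor``, otherwise λ grows and the step is retried.  Accepted-step
  MSE is therefore non-increasing by construction.
* ``scaled_conjugate_gradient`` — Møller's SCG, a Hessian-free conjugate
  gradient method with a Levenberg-style scaling parameter in place of a
  line search.

Both trainers stop at ``target_mse`` or ``max_epochs``.  With 25 training
samples and >120 free parameters the network is heavily over-parameterized;
it is used as an interpolating/extrapolating surrogate, not as a
generalizing model, and the stopping threshold is what keeps the fit tame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .core_data import COMPONENTS, TARGET, Dataset, ScalingParams

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "TrainReport",
    "init_network",
    "forward",
    "mse",
    "loss_gradient",
    "prediction_jacobian",
    "train",
    "select_hidden_size",
    "predict_production",
    "save_model",
    "load_model",
]

_ALGORITHMS = ("levenberg_marquardt", "scaled_conjugate_gradient")


@dataclass
class NetworkParams:
    """Weights and biases of an I-H-1 tanh/linear regression network."""

    hidden_weights: np.ndarray  # (H, I)
    hidden_biases: np.ndarray  # (H,)
    output_weights: np.ndarray  # (1, H)
    output_biases: np.ndarray  # (1,)
    hidden_activation: str = "tanh"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.output_biases = np.asarray(self.output_biases, dtype=float)
        H, I = self.hidden_weights.shape
        if self.hidden_biases.shape != (H,):
            raise ValueError("hidden_biases shape mismatch")
        if self.output_weights.shape != (1, H):
            raise ValueError("output_weights shape mismatch")
        if self.output_biases.shape != (1,):
            raise ValueError("output_biases shape mismatch")
        for arr in (
            self.hidden_weights,
            self.hidden_biases,
            self.output_weights,
            self.output_biases,
        ):
            if not np.isfinite(arr).all():
                raise ValueError("network parameters must be finite")
        if self.hidden_activation != "tanh" or self.output_activation != "linear":
            raise ValueError("only tanh hidden / linear output is supported")

    @property
    def n_in(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_params(self) -> int:
        return self.n_hidden * self.n_in + 2 * self.n_hidden + 1

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.hidden_weights.copy(),
            self.hidden_biases.copy(),
            self.output_weights.copy(),
            self.output_biases.copy(),
        )

    def flatten(self) -> np.ndarray:
        """Parameter vector in the order [W1, b1, W2, b2]."""
        return np.concatenate(
            [
                self.hidden_weights.ravel(),
                self.hidden_biases,
                self.output_weights.ravel(),
                self.output_biases,
            ]
        )

    def with_flat(self, theta: np.ndarray) -> "NetworkParams":
        H, I = self.hidden_weights.shape
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError("flat parameter vector has wrong length")
        k = 0
        W1 = theta[k : k + H * I].reshape(H, I)
        k += H * I
        b1 = theta[k : k + H]
        k += H
        W2 = theta[k : k + H].reshape(1, H)
        k += H
        b2 = theta[k : k + 1]
        return NetworkParams(W1, b1, W2, b2)

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_hidden": self.n_hidden,
            "n_out": 1,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "hidden_weights": self.hidden_weights.ravel().tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.ravel().tolist(),
            "output_biases": self.output_biases.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        H, I = d["n_hidden"], d["n_in"]
        return cls(
            np.asarray(d["hidden_weights"], dtype=float).reshape(H, I),
            np.asarray(d["hidden_biases"], dtype=float),
            np.asarray(d["output_weights"], dtype=float).reshape(1, H),
            np.asarray(d["output_biases"], dtype=float),
            hidden_activation=d.get("hidden_activation", "tanh"),
            output_activation=d.get("output_activation", "linear"),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Trainer selection, stopping rule and Levenberg-Marquardt damping.

    ``target_mse`` is in scaled (unit-interval) response units; 0.019 is
    the default stopping threshold for the yield surrogate.
    """

    algorithm: str = "levenberg_marquardt"
    target_mse: float = 0.019
    max_epochs: int = 1000
    seed: int = 0
    lm_lambda0: float = 1e-3
    lm_factor: float = 10.0
    lm_lambda_max: float = 1e12

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")
        if not self.target_mse > 0:
            raise ValueError("target_mse must be > 0")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not (self.lm_lambda0 > 0 and self.lm_factor > 1):
            raise ValueError("invalid LM damping parameters")


@dataclass
class TrainReport:
    """Outcome of one training run (scaled-unit MSE trajectory)."""

    final_mse: float
    epochs_run: int
    mse_history: list[float]
    converged: bool


def init_network(n_in: int, n_hidden: int, seed: int = 0) -> NetworkParams:
    """Seeded uniform initialization: weights in ±1/√fan_in, biases zero."""
    if n_in < 1 or n_hidden < 1:
        raise ValueError("n_in and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(n_in)
    lim2 = 1.0 / np.sqrt(n_hidden)
    return NetworkParams(
        hidden_weights=rng.uniform(-lim1, lim1, size=(n_hidden, n_in)),
        hidden_biases=np.zeros(n_hidden),
        output_weights=rng.uniform(-lim2, lim2, size=(1, n_hidden)),
        output_biases=np.zeros(1),
    )


def _as_matrix(x: np.ndarray, n_in: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != n_in:
        raise ValueError(f"input has {X.shape[1]} features, network expects {n_in}")
    if not np.isfinite(X).all():
        raise ValueError("inputs must be finite")
    return X, single


def forward(net: NetworkParams, x: np.ndarray):
    """Scaled prediction(s): W2·tanh(W1·x + b1) + b2 (may leave [0, 1])."""
    X, single = _as_matrix(x, net.n_in)
    h = np.tanh(X @ net.hidden_weights.T + net.hidden_biases)
    out = h @ net.output_weights.T + net.output_biases  # (n, 1)
    return float(out[0, 0]) if single else out[:, 0]


def mse(net: NetworkParams, inputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean over samples of squared prediction error."""
    X, _ = _as_matrix(np.atleast_2d(inputs), net.n_in)
    y = np.asarray(targets, dtype=float).ravel()
    if len(X) == 0 or len(y) == 0:
        raise ValueError("mse requires at least one sample")
    if len(X) != len(y):
        raise ValueError("inputs and targets have different sample counts")
    r = forward(net, X) - y
    return float(np.mean(r * r))


def prediction_jacobian(net: NetworkParams, X: np.ndarray) -> np.ndarray:
    """(n, p) Jacobian of predictions w.r.t. the flat parameter vector.

    Parameter order matches :meth:`NetworkParams.flatten`.
    """
    X, _ = _as_matrix(np.atleast_2d(X), net.n_in)
    n = X.shape[0]
    h = np.tanh(X @ net.hidden_weights.T + net.hidden_biases)  # (n, H)
    dtanh = 1.0 - h * h  # (n, H)
    w2 = net.output_weights[0]  # (H,)
    dz = dtanh * w2  # (n, H): d pred / d preactivation_j
    # d/dW1[j,i] = dz_j * x_i
    dW1 = dz[:, :, None] * X[:, None, :]  # (n, H, I)
    J = np.concatenate(
        [dW1.reshape(n, -1), dz, h, np.ones((n, 1))], axis=1
    )
    return J


def loss_gradient(
    net: NetworkParams, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Analytic gradient of the MSE loss w.r.t. the flat parameters."""
    X, _ = _as_matrix(np.atleast_2d(X), net.n_in)
    y = np.asarray(y, dtype=float).ravel()
    r = forward(net, X) - y
    J = prediction_jacobian(net, X)
    return (2.0 / len(y)) * (J.T @ r)


def _train_lm(
    net: NetworkParams, X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> tuple[NetworkParams, TrainReport]:
    theta = net.flatten()
    current = mse(net, X, y)
    history = [current]
    lam = config.lm_lambda0
    epochs = 0
    for _ in range(config.max_epochs):
        if current <= config.target_mse:
            break
        candidate = net.with_flat(theta)
        r = forward(candidate, X) - y
        J = prediction_jacobian(candidate, X)
        A = J.T @ J
        g = J.T @ r
        accepted = False
        while lam <= config.lm_lambda_max:
            try:
                delta = np.linalg.solve(A + lam * np.eye(A.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= config.lm_factor
                continue
            trial = theta + delta
            trial_net = net.with_flat(trial)
            trial_mse = mse(trial_net, X, y)
            if not np.isfinite(trial_mse):
                lam *= config.lm_factor
                continue
            if trial_mse < current:
                theta, current = trial, trial_mse
                lam = max(lam / config.lm_factor, 1e-15)
                accepted = True
                break
            lam *= config.lm_factor
        if not accepted:  # damping exhausted: local minimum to precision
            break
        epochs += 1
        history.append(current)
        if not np.isfinite(current):
            raise FloatingPointError(f"non-finite loss at epoch {epochs}")
    final = net.with_flat(theta)
    return final, TrainReport(
        final_mse=current,
        epochs_run=epochs,
        mse_history=history,
        converged=current <= config.target_mse,
    )


def _train_scg(
    net: NetworkParams, X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> tuple[NetworkParams, TrainReport]:
    # Møller's scaled conjugate gradient with the standard constants
    # (sigma = 1e-4, initial lambda = 1e-6).
    w = net.flatten()
    n_p = len(w)
    f = lambda v: mse(net.with_flat(v), X, y)
    gradf = lambda v: loss_gradient(net.with_flat(v), X, y)

    sigma0 = 1.0e-4
    lamk = 1.0e-6
    lam_bar = 0.0
    fw = f(w)
    r = -gradf(w)
    p = r.copy()
    success = True
    history = [fw]
    epochs = 0
    delta = 0.0

    for _ in range(config.max_epochs):
        if fw <= config.target_mse:
            break
        p_norm2 = float(p @ p)
        if p_norm2 <= 1e-300:
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            s = (gradf(w + sigma * p) + (r)) / sigma  # grad(w+σp) - grad(w)
            delta = float(p @ s)
        delta += (lamk - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lamk - delta / p_norm2)
            delta = -delta + lamk * p_norm2
            lamk = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        fw_new = f(w + alpha * p)
        comparison = 2.0 * delta * (fw - fw_new) / (mu * mu)
        if comparison >= 0 and np.isfinite(fw_new):
            w = w + alpha * p
            fw = fw_new
            r_new = -gradf(w)
            lam_bar = 0.0
            success = True
            epochs += 1
            history.append(fw)
            if not np.isfinite(fw):
                raise FloatingPointError(f"non-finite loss at epoch {epochs}")
            if epochs % n_p == 0:  # restart
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lamk = max(lamk / 4.0, 1e-300)
        else:
            lam_bar = lamk
            success = False
        if comparison < 0.25:
            lamk = lamk + delta * (1.0 - comparison) / p_norm2
        if lamk > 1e100:
            break
    final = net.with_flat(w)
    return final, TrainReport(
        final_mse=fw,
        epochs_run=epochs,
        mse_history=history,
        converged=fw <= config.target_mse,
    )


def train(
    net: NetworkParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[NetworkParams, TrainReport]:
    """Train on scaled pairs; returns the new network and its report.

    The input network is not modified.  With ``max_epochs=0`` the returned
    network equals the input and the report carries the initial MSE.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if len(X) == 0:
        raise ValueError("training data must be non-empty")
    if len(X) != len(y):
        raise ValueError("inputs and targets have different sample counts")
    if config.algorithm == "levenberg_marquardt":
        return _train_lm(net.copy(), X, y, config)
    return _train_scg(net.copy(), X, y, config)


def select_hidden_size(
    inputs: np.ndarray,
    targets: np.ndarray,
    candidates: Iterable[int] = range(3, 14),
    seed: int = 0,
    n_folds: int = 5,
    n_restarts: int = 3,
    config: TrainConfig | None = None,
) -> int:
    """Pick the hidden-layer width by k-fold cross-validated MSE.

    For each candidate width the CV MSE is averaged over ``n_restarts``
    random initializations per fold; the width with the smallest CV MSE
    wins, ties broken toward the smaller network.  The published surrogate
    used width 11 chosen from the 3..13 range; with 25 noisy samples the
    selection is intrinsically unstable, so treat the result as a
    reasonable width rather than a sharp optimum.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = len(X)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV")
    config = config or TrainConfig(max_epochs=200)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    best_size, best_cv = None, np.inf
    for size in candidates:
        fold_mses = []
        for k, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, val_idx)
            for r in range(n_restarts):
                init_seed = int(rng.integers(0, 2**31 - 1))
                net0 = init_network(X.shape[1], size, seed=init_seed)
                fitted, _ = train(net0, X[train_idx], y[train_idx], config)
                fold_mses.append(mse(fitted, X[val_idx], y[val_idx]))
        cv = float(np.mean(fold_mses))
        if cv < best_cv:
            best_size, best_cv = size, cv
    return int(best_size)


def predict_production(
    net: NetworkParams, scaler: ScalingParams, chromosome: np.ndarray
):
    """Predicted flavone yield (μg/mL) for raw concentration vector(s).

    Scales the nine components with the training scaler, evaluates the
    network, and inverse-scales the output with the target column's range.
    Predictions for media outside the training envelope are extrapolations
    and may exceed the training maximum (the output unit is linear).
    """
    chrom = np.asarray(chromosome, dtype=float)
    single = chrom.ndim == 1
    Xs = scaler.transform_features(np.atleast_2d(chrom))
    out = forward(net, Xs)
    raw = scaler.inverse_transform_target(np.atleast_1d(out))
    return float(raw[0]) if single else raw


def save_model(
    path: str | Path, net: NetworkParams, scaler: ScalingParams
) -> None:
    """Serialize network + scaler to a plain JSON document (round-trip exact)."""
    doc = {"network": net.to_dict(), "scaler": scaler.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> tuple[NetworkParams, ScalingParams]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return (
        NetworkParams.from_dict(doc["network"]),
        ScalingParams.from_dict(doc["scaler"]),
    )
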