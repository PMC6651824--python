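"""Single sparse auto-encoder layer with a KL sparsity penalty.

The layer is the classic sigmoid encoder/decoder pair

    h = sigmoid(W1 x + b1),      z = sigmoid(W2 h + b2)

trained to reconstruct its input under the objective

    L(X, Z) = 1/2 * sum_i ||z_i - x_i||^2  +  beta * sum_j KL(rho || rho_hat_j)

where ``rho_hat_j`` is the mean activation of hidden unit j over the whole
training set and KL is the Bernoulli Kullback-Leibler divergence
``rho ln(rho/rho_hat) + (1-rho) ln((1-rho)/(1-rho_hat))`` (natural log).
The penalty drives most hidden units towards the small target activation
``rho``, so only a few units respond to any given input.

Training is first-order gradient descent with classical momentum and
analytic gradients (validated against central finite differences in the
test suite).  The update step is scaled by 1/m so the default learning rate
is meaningful independent of the training-set size; the objective itself is
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import ValidationError

__all__ = [
    "SAEParams",
    "TrainOptions",
    "TrainingDivergedError",
    "sigmoid",
    "encode",
    "decode",
    "kl_divergence",
    "sae_loss",
    "sae_loss_and_grads",
    "train_sae",
]

_KL_EPS = 1e-10


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during gradient descent."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"training diverged at epoch {epoch} "
            f"(learning_rate={learning_rate}); reduce the learning rate"
        )


def sigmoid(u):
    """Numerically stable elementwise logistic function 1/(1+exp(-u))."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out if out.ndim else float(out)


@dataclass
class SAEParams:
    """Weights, biases and sparsity hyperparameters of one SAE layer."""

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (input, hidden)
    b2: np.ndarray  # (input,)
    rho: float = 0.05
    beta: float = 3.0

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        h, d = self.W1.shape
        if self.W2.shape != (d, h):
            raise ValidationError(
                f"W2 shape {self.W2.shape} inconsistent with W1 {self.W1.shape}"
            )
        if self.b1.shape != (h,) or self.b2.shape != (d,):
            raise ValidationError("bias shapes inconsistent with weights")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValidationError("non-finite parameter entries")
        if not (0 < self.rho < 1):
            raise ValidationError(f"rho must lie in (0,1), got {self.rho}")
        if self.beta < 0:
            raise ValidationError(f"beta must be >= 0, got {self.beta}")

    @property
    def d_input(self) -> int:
        return self.W1.shape[1]

    @property
    def d_hidden(self) -> int:
        return self.W1.shape[0]

    @classmethod
    def initialize(
        cls,
        d_input: int,
        d_hidden: int,
        rho: float = 0.05,
        beta: float = 3.0,
        seed: int = 0,
        init_scale: float = 1.0,
    ) -> "SAEParams":
        """Uniform(-r, r) init with r = init_scale * sqrt(6/(fan_in+fan_out))."""
        rng = np.random.default_rng(seed)
        r = init_scale * np.sqrt(6.0 / (d_input + d_hidden))
        return cls(
            W1=rng.uniform(-r, r, size=(d_hidden, d_input)),
            b1=np.zeros(d_hidden),
            W2=rng.uniform(-r, r, size=(d_input, d_hidden)),
            b2=np.zeros(d_input),
            rho=rho,
            beta=beta,
        )

    # JSON container (arrays as nested lists; models here are small).
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "kind": "sae_params",
            "rho": self.rho,
            "beta": self.beta,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SAEParams":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "sae_params":
            raise ValidationError(f"{path} is not an SAE parameter container")
        return cls(
            W1=np.array(payload["W1"]),
            b1=np.array(payload["b1"]),
            W2=np.array(payload["W2"]),
            b2=np.array(payload["b2"]),
            rho=payload["rho"],
            beta=payload["beta"],
        )


@dataclass
class TrainOptions:
    """Gradient-descent settings shared by SAE pretraining and fine-tuning.

    ``batch_size=None`` means full batch, the default: the sparsity penalty
    is defined through the mean activation over the whole training set, so
    full batch optimizes the exact objective.  Mini-batch mode approximates
    the mean activation with an exponential moving average (decay 0.99) and
    is therefore an approximation.
    """

    epochs: int = 200
    learning_rate: float = 0.1
    momentum: float = 0.9
    batch_size: int | None = None
    seed: int = 0
    init_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValidationError("momentum must lie in [0, 1)")


def encode(params: SAEParams, X: np.ndarray) -> np.ndarray:
    """Hidden representation sigmoid(X W1^T + b1); rows are samples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.d_input:
        raise ValidationError(
            f"input has {X.shape[1]} columns but encoder expects {params.d_input}"
        )
    return sigmoid(X @ params.W1.T + params.b1)


def decode(params: SAEParams, H: np.ndarray) -> np.ndarray:
    """Reconstruction sigmoid(H W2^T + b2)."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != params.d_hidden:
        raise ValidationError(
            f"hidden input has {H.shape[1]} columns but decoder expects "
            f"{params.d_hidden}"
        )
    return sigmoid(H @ params.W2.T + params.b2)


def kl_divergence(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over hidden units of the Bernoulli KL divergence KL(rho || rho_hat_j).

    Non-negative, zero iff every ``rho_hat_j == rho``.  ``rho_hat`` is clamped
    to ``[1e-10, 1 - 1e-10]`` so saturated units do not produce infinities.
    """
    if not (0 < rho < 1):
        raise ValidationError(f"rho must lie in (0,1), got {rho}")
    rh = np.clip(np.asarray(rho_hat, dtype=float), _KL_EPS, 1.0 - _KL_EPS)
    return float(
        np.sum(rho * np.log(rho / rh) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rh)))
    )


def _check_scaled(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size and (X.min() < 0.0 or X.max() > 1.0):
        raise ValidationError(
            "input entries outside [0,1]; apply scale_to_unit_interval first "
            "(a sigmoid decoder cannot reconstruct unbounded absorbance)"
        )
    return X


def sae_loss(params: SAEParams, X: np.ndarray) -> tuple[float, float, float]:
    """Total, reconstruction and sparsity components of the SAE objective."""
    X = _check_scaled(X)
    H = encode(params, X)
    Z = decode(params, H)
    recon = 0.5 * float(np.sum((Z - X) ** 2))
    rho_hat = H.mean(axis=0)
    sparsity = params.beta * kl_divergence(params.rho, rho_hat)
    return recon + sparsity, recon, sparsity


def sae_loss_and_grads(
    params: SAEParams, X: np.ndarray, rho_hat_override: np.ndarray | None = None
) -> tuple[tuple[float, float, float], dict[str, np.ndarray]]:
    """Loss components plus analytic gradients w.r.t. every parameter block.

    ``rho_hat_override`` substitutes an externally tracked mean activation
    (the mini-batch EMA); by default the batch mean is used, which on the
    full training set is the exact objective.
    """
    X = _check_scaled(X)
    m = X.shape[0]
    H = encode(params, X)
    Z = decode(params, H)

    rho_hat = H.mean(axis=0) if rho_hat_override is None else rho_hat_override
    rho_hat = np.clip(rho_hat, _KL_EPS, 1.0 - _KL_EPS)
    recon = 0.5 * float(np.sum((Z - X) ** 2))
    sparsity = params.beta * kl_divergence(params.rho, rho_hat)

    dB = (Z - X) * Z * (1.0 - Z)  # d recon / d (pre-sigmoid decoder input)
    gW2 = dB.T @ H
    gb2 = dB.sum(axis=0)
    # KL'(rho_hat_j) spread evenly over the m samples that form the mean.
    dkl = (-params.rho / rho_hat + (1.0 - params.rho) / (1.0 - rho_hat))
    dH = dB @ params.W2 + (params.beta / m) * dkl[None, :]
    dA = dH * H * (1.0 - H)
    gW1 = dA.T @ X
    gb1 = dA.sum(axis=0)

    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}
    return (recon + sparsity, recon, sparsity), grads


def train_sae(
    X: np.ndarray,
    d_hidden: int,
    rho: float = 0.05,
    beta: float = 3.0,
    opts: TrainOptions | None = None,
) -> tuple[SAEParams, list[float]]:
    """Train one sparse auto-encoder layer by gradient descent.

    Returns the trained parameters and the per-epoch total loss history.
    Deterministic for a fixed ``opts.seed``.  Raises
    :class:`TrainingDivergedError` if the loss leaves the finite range.
    """
    opts = opts or TrainOptions()
    X = _check_scaled(X)
    if d_hidden < 1:
        raise ValidationError(f"d_hidden must be >= 1, got {d_hidden}")
    m = X.shape[0]
    params = SAEParams.initialize(
        X.shape[1], d_hidden, rho=rho, beta=beta,
        seed=opts.seed, init_scale=opts.init_scale,
    )
    rng = np.random.default_rng(opts.seed + 1)
    history: list[float] = []
    ema_rho_hat: np.ndarray | None = None
    velocity = {k: 0.0 for k in ("W1", "b1", "W2", "b2")}

    for epoch in range(opts.epochs):
        if opts.batch_size is None:
            (total, _, _), grads = sae_loss_and_grads(params, X)
            _apply(params, grads, opts.learning_rate / m, opts.momentum, velocity)
        else:
            order = rng.permutation(m)
            for start in range(0, m, opts.batch_size):
                batch = X[order[start : start + opts.batch_size]]
                batch_rho = encode(params, batch).mean(axis=0)
                ema_rho_hat = (
                    batch_rho
                    if ema_rho_hat is None
                    else 0.99 * ema_rho_hat + 0.01 * batch_rho
                )
                _, grads = sae_loss_and_grads(
                    params, batch, rho_hat_override=ema_rho_hat
                )
                _apply(
                    params, grads, opts.learning_rate / batch.shape[0],
                    opts.momentum, velocity,
                )
            total, _, _ = sae_loss(params, X)
        if not np.isfinite(total):
            raise TrainingDivergedError(epoch, opts.learning_rate)
        history.append(float(total))
    return params, history


def _apply(
    params: SAEParams,
    grads: dict[str, np.ndarray],
    step: float,
    momentum: float,
    velocity: dict,
) -> None:
    # classical momentum: v <- mu v - eta g; param <- param + v
    for key in ("W1", "b1", "W2", "b2"):
        velocity[key] = momentum * velocity[key] - step * grads[key]
        arr = getattr(params, key)
        arr += velocity[key]
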