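"""Stacked sparse auto-encoder with a softmax read-out.

The stack is built greedily: the first SAE is trained to reconstruct the
scaled spectra, the second to reconstruct the first layer's hidden codes,
and so on.  Decoders are discarded after pretraining; the retained encoder
chain maps a spectrum to its deepest code, on which a softmax classifier

    P(y = j | x) = exp(theta_j^T f) / sum_l exp(theta_l^T f)

is trained by minimizing the multinomial cross-entropy with L2 weight decay
on the softmax parameters,

    J(theta) = -(1/m) sum_i log P(y_i | x_i)  +  (lambda/2) ||theta||^2.

Fine-tuning backpropagates J through the whole encoder chain, so both the
softmax parameters and every encoder weight move ("fine-tune the entire
network").  A bias is carried by augmenting the deepest code with a
constant-1 feature.  All gradients are analytic, full-batch, and checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import ValidationError
from .sae import (
    SAEParams,
    TrainOptions,
    TrainingDivergedError,
    sigmoid,
    train_sae,
)

__all__ = [
    "SSAEModel",
    "stack_pretrain",
    "softmax_probs",
    "supervised_loss",
    "supervised_loss_and_grads",
    "fine_tune",
    "predict",
    "fit_ssae",
]


@dataclass
class SSAEModel:
    """Encoder chain plus softmax parameters.

    ``encoder_layers`` is an ordered list of ``(W, b)`` pairs; ``theta`` has
    one row per class and one column per deepest-code feature plus a final
    bias column.  ``lambda_decay`` is the weight-decay coefficient applied to
    ``theta`` only (the decay term in the supervised objective penalizes the
    softmax parameters, not the encoder weights).
    """

    encoder_layers: list[tuple[np.ndarray, np.ndarray]]
    theta: np.ndarray | None = None
    lambda_decay: float = 1e-4

    def __post_init__(self) -> None:
        self.encoder_layers = [
            (np.asarray(W, dtype=float), np.asarray(b, dtype=float).ravel())
            for W, b in self.encoder_layers
        ]
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.encoder_layers:
            raise ValidationError("model has no encoder layers")
        prev = self.encoder_layers[0][0].shape[1]
        for i, (W, b) in enumerate(self.encoder_layers):
            if W.shape[1] != prev:
                raise ValidationError(
                    f"layer {i} expects {W.shape[1]} inputs but receives {prev}"
                )
            if b.shape != (W.shape[0],):
                raise ValidationError(f"layer {i} bias shape mismatch")
            prev = W.shape[0]
        if self.lambda_decay < 0:
            raise ValidationError("lambda_decay must be >= 0")
        if self.theta is not None:
            if self.theta.ndim != 2 or self.theta.shape[0] < 2:
                raise ValidationError("theta must be (k >= 2) x (features + 1)")
            if self.theta.shape[1] != prev + 1:
                raise ValidationError(
                    f"theta has {self.theta.shape[1]} columns, expected "
                    f"{prev + 1} (deepest code + bias)"
                )

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(W.shape[0] for W, _ in self.encoder_layers)

    @property
    def d_input(self) -> int:
        return self.encoder_layers[0][0].shape[1]

    @property
    def n_classes(self) -> int:
        if self.theta is None:
            raise ValidationError("model has no trained softmax layer")
        return self.theta.shape[0]

    def activations(self, X: np.ndarray) -> list[np.ndarray]:
        """Per-layer sigmoid activations, input first element excluded."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d_input:
            raise ValidationError(
                f"input has {X.shape[1]} columns, model expects {self.d_input}"
            )
        acts = []
        F = X
        for W, b in self.encoder_layers:
            F = sigmoid(F @ W.T + b)
            acts.append(F)
        return acts

    def features(self, X: np.ndarray) -> np.ndarray:
        """Deepest encoder code for each sample."""
        return self.activations(X)[-1]

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "kind": "ssae_model",
            "lambda_decay": self.lambda_decay,
            "layers": [
                {"W": W.tolist(), "b": b.tolist()} for W, b in self.encoder_layers
            ],
            "theta": None if self.theta is None else self.theta.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SSAEModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "ssae_model":
            raise ValidationError(f"{path} is not an SSAE model container")
        return cls(
            encoder_layers=[
                (np.array(l["W"]), np.array(l["b"])) for l in payload["layers"]
            ],
            theta=None if payload["theta"] is None else np.array(payload["theta"]),
            lambda_decay=payload["lambda_decay"],
        )


def stack_pretrain(
    X: np.ndarray,
    layer_sizes: Sequence[int],
    rho: float = 0.05,
    beta: float = 3.0,
    opts: TrainOptions | Sequence[TrainOptions] | None = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[list[float]]]:
    """Greedy layerwise pretraining; each SAE reads the previous hidden code.

    Returns the encoder ``(W, b)`` pairs (decoders discarded) and the loss
    history of every layer.  ``opts`` may be a single option set reused for
    every layer or one per layer.
    """
    layer_sizes = [int(s) for s in layer_sizes]
    if not layer_sizes:
        raise ValidationError("layer_sizes must be non-empty")
    if opts is None or isinstance(opts, TrainOptions):
        opts_list = [opts or TrainOptions()] * len(layer_sizes)
    else:
        opts_list = list(opts)
        if len(opts_list) != len(layer_sizes):
            raise ValidationError("one TrainOptions per layer required")

    layers: list[tuple[np.ndarray, np.ndarray]] = []
    histories: list[list[float]] = []
    current = np.atleast_2d(np.asarray(X, dtype=float))
    for i, (size, layer_opts) in enumerate(zip(layer_sizes, opts_list)):
        try:
            params, hist = train_sae(current, size, rho=rho, beta=beta, opts=layer_opts)
        except TrainingDivergedError as exc:
            raise TrainingDivergedError(exc.epoch, exc.learning_rate) from exc
        layers.append((params.W1.copy(), params.b1.copy()))
        histories.append(hist)
        current = sigmoid(current @ params.W1.T + params.b1)
    return layers, histories


def softmax_probs(theta: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Row-stochastic class probabilities exp(theta_j.f) / sum_l exp(theta_l.f).

    Computed with max-subtraction so large scores do not overflow.
    """
    theta = np.asarray(theta, dtype=float)
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != theta.shape[1]:
        raise ValidationError(
            f"features have {F.shape[1]} columns but theta expects {theta.shape[1]}"
        )
    S = F @ theta.T
    S -= S.max(axis=1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=1, keepdims=True)


def _augment(F: np.ndarray) -> np.ndarray:
    return np.hstack([F, np.ones((F.shape[0], 1))])


def _check_labels(y: np.ndarray, k: int) -> np.ndarray:
    y = np.asarray(y, dtype=int).ravel()
    if y.size and (y.min() < 0 or y.max() >= k):
        raise ValidationError(f"label outside 0..{k - 1}")
    return y


def supervised_loss(model: SSAEModel, X: np.ndarray, y: np.ndarray) -> float:
    """Cross-entropy through the full encoder stack plus softmax weight decay."""
    loss, _ = supervised_loss_and_grads(model, X, y)
    return loss


def supervised_loss_and_grads(
    model: SSAEModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, dict]:
    """Loss plus analytic gradients for theta, every encoder layer, and X.

    The returned dict carries ``theta``, ``layers`` (list of (gW, gb)) and
    ``input`` — the per-sample gradient matrix d J / d X, which is what the
    guided-backward saliency aggregates.
    """
    if model.theta is None:
        raise ValidationError("model has no softmax layer; fine-tune first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_labels(y, model.n_classes)
    m = X.shape[0]
    acts = model.activations(X)
    Faug = _augment(acts[-1])
    P = softmax_probs(model.theta, Faug)

    eps = 1e-300  # guards the log only; gradients use the fused (P - Y) form
    ll = -np.mean(np.log(np.maximum(P[np.arange(m), y], eps)))
    loss = float(ll + 0.5 * model.lambda_decay * np.sum(model.theta**2))

    Y = np.zeros_like(P)
    Y[np.arange(m), y] = 1.0
    G = (P - Y) / m
    g_theta = G.T @ Faug + model.lambda_decay * model.theta

    dF = G @ model.theta[:, :-1]
    layer_grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(  # type: ignore
        model.encoder_layers
    )
    for li in range(len(model.encoder_layers) - 1, -1, -1):
        F = acts[li]
        F_prev = X if li == 0 else acts[li - 1]
        dA = dF * F * (1.0 - F)
        layer_grads[li] = (dA.T @ F_prev, dA.sum(axis=0))
        dF = dA @ model.encoder_layers[li][0]
    return loss, {"theta": g_theta, "layers": layer_grads, "input": dF}


def fine_tune(
    model: SSAEModel, X: np.ndarray, y: np.ndarray, opts: TrainOptions | None = None
) -> tuple[SSAEModel, list[float]]:
    """Supervised fine-tuning of theta and all encoder weights, full batch.

    ``theta`` is initialized to zeros (uniform initial probabilities) when
    absent.  Returns the updated model and the per-epoch loss history;
    deterministic given the model and options.
    """
    opts = opts or TrainOptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    k = int(y.max()) + 1
    if model.theta is None:
        model.theta = np.zeros((max(k, 2), model.layer_sizes[-1] + 1))
    y = _check_labels(y, model.n_classes)

    history: list[float] = []
    v_theta = 0.0
    v_layers = [(0.0, 0.0)] * len(model.encoder_layers)
    mu, lr = opts.momentum, opts.learning_rate
    for epoch in range(opts.epochs):
        loss, grads = supervised_loss_and_grads(model, X, y)
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch, lr)
        v_theta = mu * v_theta - lr * grads["theta"]
        model.theta += v_theta
        for li, ((W, b), (gW, gb)) in enumerate(
            zip(model.encoder_layers, grads["layers"])
        ):
            vW, vb = v_layers[li]
            vW = mu * vW - lr * gW
            vb = mu * vb - lr * gb
            W += vW
            b += vb
            v_layers[li] = (vW, vb)
        history.append(loss)
    return model, history


def predict(model: SSAEModel, X: np.ndarray) -> np.ndarray:
    """Most probable class per sample; ties go to the smallest class index."""
    if model.theta is None:
        raise ValidationError("model has no softmax layer; fine-tune first")
    P = softmax_probs(model.theta, _augment(model.features(X)))
    return np.argmax(P, axis=1)  # argmax takes the first (smallest) index on ties


def fit_ssae(
    X: np.ndarray,
    y: np.ndarray,
    layer_sizes: Sequence[int],
    rho: float = 0.05,
    beta: float = 3.0,
    lambda_decay: float = 1e-4,
    pretrain_opts: TrainOptions | None = None,
    finetune_opts: TrainOptions | None = None,
) -> SSAEModel:
    """Convenience: greedy pretraining followed by supervised fine-tuning."""
    layers, _ = stack_pretrain(X, layer_sizes, rho=rho, beta=beta, opts=pretrain_opts)
    model = SSAEModel(encoder_layers=layers, lambda_decay=lambda_decay)
    model, _ = fine_tune(model, X, y, opts=finetune_opts)
    return model
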