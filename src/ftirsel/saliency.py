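"""Guided-backward saliency: gradient of the supervised loss w.r.t. the spectrum.

A trained stack plus softmax defines a differentiable map from an input
spectrum to the cross-entropy loss.  The gradient of that loss with respect
to the input — obtained by chaining the softmax Jacobian and every sigmoid
encoder layer back to the spectrum — scores each wavenumber by how strongly
a small absorbance change there would move the classifier's loss.  Large
|gradient| marks discriminative wavenumbers; selection keeps the strong
peaks and valleys of the normalized curve (|value| above a threshold at a
local extremum of |value|), which is how a handful of optimal wavenumbers
is distilled from a several-thousand-point axis.

For a single sample with true class ``y`` the chain starts from
``d loss / d f = p - e_y`` (softmax probabilities minus the one-hot target),
an algebraically fused form of "d loss / d P times d P / d f" that is exact
and needs no clamping of small probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .dataset import ValidationError
from .ssae import SSAEModel, softmax_probs, supervised_loss_and_grads

__all__ = [
    "GuidedSaliency",
    "SelectionResult",
    "softmax_input_jacobian",
    "guided_backward",
    "softmax_feature_saliency",
    "select_wavenumbers",
    "selection_fraction",
]

AGGREGATIONS = ("mean", "mean_abs", "class_mean_max")


@dataclass
class GuidedSaliency:
    """Per-wavenumber importance scores.

    ``raw`` is the aggregated input gradient; ``normalized`` is ``raw``
    divided by its maximum magnitude so the curve spans [-1, 1] (all-zero
    saliency stays all-zero).
    """

    raw: np.ndarray
    normalized: np.ndarray
    aggregation: str
    n_samples_used: int

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float).ravel()
        self.normalized = np.asarray(self.normalized, dtype=float).ravel()
        if self.raw.shape != self.normalized.shape:
            raise ValidationError("raw and normalized saliency lengths differ")
        if np.any(self.raw != 0):
            if not np.isclose(np.max(np.abs(self.normalized)), 1.0):
                raise ValidationError("normalized saliency must peak at |1|")


@dataclass
class SelectionResult:
    """A sorted set of selected wavenumber indices with provenance."""

    method: str
    indices: np.ndarray
    wavenumbers: np.ndarray | None = None
    threshold: float | None = None
    count: int | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        if np.unique(idx).size != idx.size:
            raise ValidationError("selected indices must be unique")
        self.indices = np.sort(idx)
        if self.wavenumbers is not None:
            wn = np.asarray(self.wavenumbers, dtype=float).ravel()
            if wn.size != self.indices.size:
                raise ValidationError("wavenumbers inconsistent with indices")
            self.wavenumbers = wn

    @property
    def n_selected(self) -> int:
        return self.indices.size


def normalize_saliency(raw: np.ndarray) -> np.ndarray:
    """Scale to max |value| = 1; identically-zero input stays zero.

    Idempotent: normalizing an already normalized curve changes nothing.
    """
    raw = np.asarray(raw, dtype=float).ravel()
    peak = np.max(np.abs(raw)) if raw.size else 0.0
    return raw / peak if peak > 0 else raw.copy()


def softmax_input_jacobian(
    theta: np.ndarray, features: np.ndarray, j: int
) -> np.ndarray:
    """Exact gradient of the softmax probability P_j w.r.t. its input features.

    Uses the stable product form ``P_j (theta_j - sum_l P_l theta_l)``, the
    algebraic collapse of ``sum_l P_j P_l (theta_j - theta_l)``; agreement
    with finite differences of :func:`softmax_probs` is asserted in the
    test suite.
    """
    theta = np.asarray(theta, dtype=float)
    f = np.asarray(features, dtype=float).ravel()
    if f.size != theta.shape[1]:
        raise ValidationError(
            f"feature length {f.size} does not match theta columns {theta.shape[1]}"
        )
    if not (0 <= j < theta.shape[0]):
        raise ValidationError(f"class index {j} outside 0..{theta.shape[0] - 1}")
    p = softmax_probs(theta, f[None, :])[0]
    return p[j] * (theta[j] - p @ theta)


def guided_backward(
    model: SSAEModel,
    X: np.ndarray,
    y: np.ndarray,
    aggregation: str = "class_mean_max",
) -> GuidedSaliency:
    """Backpropagate the supervised loss to the input spectra and aggregate.

    Per sample the gradient of the cross-entropy w.r.t. the input is chained
    through the softmax and every encoder layer.  Aggregations across
    samples:

    - ``class_mean_max`` (default): per-class signed mean, then the
      elementwise max over class magnitudes (sign of the winning class
      kept) — every class's salient wavenumbers survive, where a global
      signed mean would cancel class-opposite gradients;
    - ``mean``: signed mean of per-sample gradients;
    - ``mean_abs``: mean of absolute per-sample gradients.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"unknown aggregation '{aggregation}'")
    if model.theta is None:
        raise ValidationError("model has no softmax layer; fine-tune first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    m = X.shape[0]

    # d J / d X has rows (1/m) * d loss_i / d x_i; undo the 1/m to get
    # per-sample gradients, then aggregate by the configured rule.
    _, grads = supervised_loss_and_grads(model, X, y)
    per_sample = m * grads["input"]

    if aggregation == "mean":
        raw = per_sample.mean(axis=0)
    elif aggregation == "mean_abs":
        raw = np.abs(per_sample).mean(axis=0)
    else:  # class_mean_max
        class_means = np.stack(
            [per_sample[y == c].mean(axis=0) for c in np.unique(y)]
        )
        winner = np.argmax(np.abs(class_means), axis=0)
        raw = class_means[winner, np.arange(class_means.shape[1])]
    return GuidedSaliency(
        raw=raw,
        normalized=normalize_saliency(raw),
        aggregation=aggregation,
        n_samples_used=m,
    )


def softmax_feature_saliency(
    model: SSAEModel, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Mean loss gradient w.r.t. the softmax *input features* (not the spectrum).

    Comparison mode: it stops the backward pass at the deepest code, i.e. it
    treats the softmax as if it acted on its input directly instead of
    chaining through the encoder layers.  Length equals the deepest code
    dimension, not the wavenumber axis.
    """
    if model.theta is None:
        raise ValidationError("model has no softmax layer; fine-tune first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    F = model.features(X)
    Faug = np.hstack([F, np.ones((F.shape[0], 1))])
    P = softmax_probs(model.theta, Faug)
    Y = np.zeros_like(P)
    Y[np.arange(X.shape[0]), y] = 1.0
    return ((P - Y) @ model.theta[:, :-1]).mean(axis=0)


def _local_extrema_mask(a: np.ndarray) -> np.ndarray:
    """Local maxima of |curve|, plateau ties resolved to the leftmost index."""
    keep = np.zeros(a.size, dtype=bool)
    if a.size == 1:
        keep[0] = True
        return keep
    left_ok = np.empty(a.size, dtype=bool)
    right_ok = np.empty(a.size, dtype=bool)
    left_ok[0] = True
    left_ok[1:] = a[1:] > a[:-1]  # strictly above the left neighbour
    right_ok[-1] = True
    right_ok[:-1] = a[:-1] >= a[1:]
    return left_ok & right_ok


def select_wavenumbers(
    saliency: GuidedSaliency,
    threshold: float = 0.5,
    wavenumbers: np.ndarray | None = None,
) -> SelectionResult:
    """Keep local extrema of the normalized saliency with |value| > threshold.

    "Peaks and valleys": an index survives only if its |normalized| value is
    a local maximum of the magnitude curve (plateaus keep their leftmost
    point) and exceeds the threshold.  Raising the threshold can only remove
    indices.  All-zero saliency yields a valid empty selection.
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    a = np.abs(saliency.normalized)
    mask = _local_extrema_mask(a) & (a > threshold)
    idx = np.flatnonzero(mask)
    wn = None
    if wavenumbers is not None:
        wavenumbers = np.asarray(wavenumbers, dtype=float).ravel()
        if wavenumbers.size != a.size:
            raise ValidationError("wavenumber axis length differs from saliency")
        wn = wavenumbers[idx]
    return SelectionResult(
        method="ssae-gb", indices=idx, wavenumbers=wn, threshold=float(threshold)
    )


def selection_fraction(n_selected: int, n_total: int) -> float:
    """Selected share of the axis as a percentage, rounded to 3 decimals."""
    if n_total <= 0:
        raise ValidationError(f"n_total must be positive, got {n_total}")
    if not (0 <= n_selected <= n_total):
        raise ValidationError("n_selected outside 0..n_total")
    return round(100.0 * n_selected / n_total, 3)
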