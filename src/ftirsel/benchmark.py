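"""Cross-validated benchmarking: KNN, RBF-SVM, SSAE, selection metrics, t-SNE.

The reporting convention follows the three-fold protocol common in
chemometric classification papers: within each fold the two training folds
form the *calibration set* and the held-out fold the *prediction set*;
accuracies are reported per fold and as the fold mean, in percent.

Two protocols coexist deliberately:

- :func:`knn_cv` / :func:`svm_grid` pick one hyperparameter setting by the
  mean held-out accuracy over the outer folds — the single-(k) /
  single-(c, g) reporting style of the study design this mirrors;
- :func:`table_report` performs the leakage-free variant, searching
  hyperparameters by an inner cross validation on each fold's calibration
  rows only, so the held-out labels can never influence the chosen setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .dataset import (
    FoldAssignment,
    SpectralDataset,
    ValidationError,
    make_folds,
    scale_to_unit_interval,
)
from .saliency import SelectionResult
from .sae import TrainOptions
from .ssae import fit_ssae, predict

__all__ = [
    "CVReport",
    "SelectionQuality",
    "accuracy",
    "knn_predict",
    "knn_cv",
    "svm_grid",
    "ssae_cv",
    "table_report",
    "selection_quality",
    "tsne_embed",
]

DEFAULT_K_GRID = tuple(range(3, 21))
DEFAULT_EXPONENTS = tuple(range(-8, 9))


@dataclass
class CVReport:
    """Fold-wise calibration/prediction accuracies for one model."""

    model: str
    params: object
    fold_calibration: list[float]
    fold_prediction: list[float]

    @property
    def mean_calibration(self) -> float:
        return float(np.mean(self.fold_calibration))

    @property
    def mean_prediction(self) -> float:
        return float(np.mean(self.fold_prediction))

    def as_frame(self) -> pd.DataFrame:
        k = len(self.fold_calibration)
        rows = {}
        for i in range(k):
            rows[f"fold {i + 1}"] = [self.fold_calibration[i], self.fold_prediction[i]]
        rows["mean"] = [self.mean_calibration, self.mean_prediction]
        return pd.DataFrame(
            rows, index=["calibration set (%)", "prediction set (%)"]
        ).round(1)

    def __str__(self) -> str:
        return f"{self.model} (params={self.params})\n{self.as_frame()}"


@dataclass
class SelectionQuality:
    """Recall/precision of a selection against planted ground truth."""

    recall: float
    precision: float
    n_selected: int
    empty_selection: bool = False


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Percentage of matching labels."""
    predicted = np.asarray(predicted).ravel()
    true = np.asarray(true).ravel()
    if predicted.size != true.size:
        raise ValidationError(
            f"length mismatch: {predicted.size} predictions for {true.size} labels"
        )
    return 100.0 * float(np.mean(predicted == true))


# ---------------------------------------------------------------------------
# KNN with documented tie-breaking
# ---------------------------------------------------------------------------


def knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    """Euclidean k-nearest-neighbour vote.

    Vote ties are broken by the tied class whose nearest representative is
    closest to the query; residual ties go to the smaller class index (the
    stable distance sort makes both rules deterministic).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train, dtype=int).ravel()
    if not (1 <= k <= X_train.shape[0]):
        raise ValidationError(f"k must lie in 1..{X_train.shape[0]}, got {k}")
    D = cdist(X_test, X_train)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = np.empty(X_test.shape[0], dtype=int)
    n_cls = int(y_train.max()) + 1
    for i in range(X_test.shape[0]):
        votes = y_train[order[i]]
        counts = np.bincount(votes, minlength=n_cls)
        winners = np.flatnonzero(counts == counts.max())
        if winners.size == 1:
            out[i] = winners[0]
        else:
            for cls in votes:  # nearest-first scan; first tied class wins
                if cls in winners:
                    out[i] = cls
                    break
    return out


def knn_cv(
    dataset: SpectralDataset,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    folds: FoldAssignment | None = None,
) -> CVReport:
    """Choose k by mean held-out accuracy over the folds and report it.

    Infeasible k values (not below the smallest calibration-fold size) are
    skipped; a note would be meaningless since the report names the winner.
    Ties between k values go to the smaller k.
    """
    if folds is None:
        folds = make_folds(dataset.labels, 3, seed=0)
    X, y = dataset.absorbance, dataset.labels
    smallest_cal = min(
        folds.calibration_rows(f).size for f in range(folds.n_folds)
    )
    feasible = [k for k in k_grid if k <= smallest_cal]
    if not feasible:
        raise ValidationError("no feasible k in the grid")

    best_k, best_mean = None, -np.inf
    for k in sorted(feasible):
        mean_pred = np.mean(
            [
                accuracy(
                    knn_predict(
                        X[folds.calibration_rows(f)],
                        y[folds.calibration_rows(f)],
                        X[folds.prediction_rows(f)],
                        k,
                    ),
                    y[folds.prediction_rows(f)],
                )
                for f in range(folds.n_folds)
            ]
        )
        if mean_pred > best_mean:
            best_k, best_mean = k, mean_pred

    cal_acc, pred_acc = [], []
    for f in range(folds.n_folds):
        cal, pred = folds.calibration_rows(f), folds.prediction_rows(f)
        cal_acc.append(accuracy(knn_predict(X[cal], y[cal], X[cal], best_k), y[cal]))
        pred_acc.append(accuracy(knn_predict(X[cal], y[cal], X[pred], best_k), y[pred]))
    return CVReport("KNN", {"k": best_k}, cal_acc, pred_acc)


# ---------------------------------------------------------------------------
# RBF-SVM grid search
# ---------------------------------------------------------------------------


def _svm_fit_predict(Xtr, ytr, Xte, c, g):
    model = SVC(C=c, gamma=g, kernel="rbf")  # one-vs-one multi-class
    model.fit(Xtr, ytr)
    return model.predict(Xte), model


def svm_grid(
    dataset: SpectralDataset,
    c_exponents: Sequence[int] = DEFAULT_EXPONENTS,
    g_exponents: Sequence[int] = DEFAULT_EXPONENTS,
    folds: FoldAssignment | None = None,
) -> CVReport:
    """RBF-SVM over the 2^-8 .. 2^8 grid of penalty c and kernel width g.

    The winner is the (c, g) with the highest mean held-out accuracy; ties
    break toward the smaller c, then the smaller g.
    """
    if folds is None:
        folds = make_folds(dataset.labels, 3, seed=0)
    if not len(c_exponents) or not len(g_exponents):
        raise ValidationError("exponent ranges must be non-empty")
    X, y = dataset.absorbance, dataset.labels

    splits = [
        (folds.calibration_rows(f), folds.prediction_rows(f))
        for f in range(folds.n_folds)
    ]
    best, best_mean = None, -np.inf
    for ce in sorted(c_exponents):
        for ge in sorted(g_exponents):
            c, g = 2.0**ce, 2.0**ge
            mean_pred = np.mean(
                [
                    accuracy(_svm_fit_predict(X[cal], y[cal], X[pred], c, g)[0], y[pred])
                    for cal, pred in splits
                ]
            )
            if mean_pred > best_mean:
                best, best_mean = (c, g), mean_pred

    c, g = best
    cal_acc, pred_acc = [], []
    for cal, pred in splits:
        preds, model = _svm_fit_predict(X[cal], y[cal], X[pred], c, g)
        cal_acc.append(accuracy(model.predict(X[cal]), y[cal]))
        pred_acc.append(accuracy(preds, y[pred]))
    return CVReport("SVM", {"c": c, "g": g}, cal_acc, pred_acc)


# ---------------------------------------------------------------------------
# SSAE cross validation
# ---------------------------------------------------------------------------


def ssae_cv(
    dataset: SpectralDataset,
    layer_sizes: Sequence[int] = (64, 13),
    folds: FoldAssignment | None = None,
    rho: float = 0.05,
    beta: float = 3.0,
    lambda_decay: float = 1e-4,
    pretrain_opts: TrainOptions | None = None,
    finetune_opts: TrainOptions | None = None,
) -> CVReport:
    """Per-fold SSAE training and evaluation.

    Absorbance is scaled into the sigmoid-reconstructable range using the
    calibration rows only; the held-out rows are transformed with the same
    record (clipped to [0, 1] where they fall outside the calibration range).
    """
    if folds is None:
        folds = make_folds(dataset.labels, 3, seed=0)
    cal_acc, pred_acc = [], []
    for f in range(folds.n_folds):
        cal, pred = folds.calibration_rows(f), folds.prediction_rows(f)
        cal_ds = dataset.subset_rows(cal)
        scaled, record = scale_to_unit_interval(cal_ds)
        X_cal = scaled.absorbance
        X_pred = np.clip(record.apply(dataset.absorbance[pred]), 0.0, 1.0)
        model = fit_ssae(
            X_cal,
            cal_ds.labels,
            layer_sizes,
            rho=rho,
            beta=beta,
            lambda_decay=lambda_decay,
            pretrain_opts=pretrain_opts,
            finetune_opts=finetune_opts,
        )
        cal_acc.append(accuracy(predict(model, X_cal), cal_ds.labels))
        pred_acc.append(accuracy(predict(model, X_pred), dataset.labels[pred]))
    return CVReport("SSAE", {"layer_sizes": tuple(layer_sizes)}, cal_acc, pred_acc)


# ---------------------------------------------------------------------------
# Table-style reporting with nested (leakage-free) hyperparameter search
# ---------------------------------------------------------------------------


def table_report(
    dataset: SpectralDataset,
    model_spec: dict,
    selection: SelectionResult | None = None,
    folds: FoldAssignment | None = None,
) -> CVReport:
    """Full protocol on the full spectrum or a selected-wavenumber subset.

    ``model_spec`` is ``{"name": "knn", "k_grid": ...}`` or
    ``{"name": "svm", "c_exponents": ..., "g_exponents": ...}``.  Within
    each outer fold the hyperparameter is chosen by a 3-fold inner cross
    validation on the calibration rows only, then the model is refit on the
    whole calibration split and evaluated on the prediction split.
    """
    if folds is None:
        folds = make_folds(dataset.labels, 3, seed=0)
    if selection is not None:
        if selection.n_selected == 0:
            raise ValidationError("empty selection cannot be benchmarked")
        dataset = dataset.restrict(selection.indices)
    name = model_spec["name"].lower()
    X, y = dataset.absorbance, dataset.labels

    chosen: list[object] = []
    cal_acc, pred_acc = [], []
    for f in range(folds.n_folds):
        cal, pred = folds.calibration_rows(f), folds.prediction_rows(f)
        inner = make_folds(y[cal], 3, seed=folds.seed + 1000 + f)
        if name == "knn":
            grid = model_spec.get("k_grid", DEFAULT_K_GRID)
            smallest = min(
                inner.calibration_rows(g).size for g in range(inner.n_folds)
            )
            best, best_mean = None, -np.inf
            for k in sorted(kk for kk in grid if kk <= smallest):
                mean_pred = np.mean(
                    [
                        accuracy(
                            knn_predict(
                                X[cal][inner.calibration_rows(g)],
                                y[cal][inner.calibration_rows(g)],
                                X[cal][inner.prediction_rows(g)],
                                k,
                            ),
                            y[cal][inner.prediction_rows(g)],
                        )
                        for g in range(inner.n_folds)
                    ]
                )
                if mean_pred > best_mean:
                    best, best_mean = k, mean_pred
            chosen.append({"k": best})
            cal_acc.append(accuracy(knn_predict(X[cal], y[cal], X[cal], best), y[cal]))
            pred_acc.append(
                accuracy(knn_predict(X[cal], y[cal], X[pred], best), y[pred])
            )
        elif name == "svm":
            ces = model_spec.get("c_exponents", DEFAULT_EXPONENTS)
            ges = model_spec.get("g_exponents", DEFAULT_EXPONENTS)
            best, best_mean = None, -np.inf
            for ce in sorted(ces):
                for ge in sorted(ges):
                    c, g = 2.0**ce, 2.0**ge
                    mean_pred = np.mean(
                        [
                            accuracy(
                                _svm_fit_predict(
                                    X[cal][inner.calibration_rows(gg)],
                                    y[cal][inner.calibration_rows(gg)],
                                    X[cal][inner.prediction_rows(gg)],
                                    c,
                                    g,
                                )[0],
                                y[cal][inner.prediction_rows(gg)],
                            )
                            for gg in range(inner.n_folds)
                        ]
                    )
                    if mean_pred > best_mean:
                        best, best_mean = (c, g), mean_pred
            c, g = best
            chosen.append({"c": c, "g": g})
            preds, model = _svm_fit_predict(X[cal], y[cal], X[pred], c, g)
            cal_acc.append(accuracy(model.predict(X[cal]), y[cal]))
            pred_acc.append(accuracy(preds, y[pred]))
        else:
            raise ValidationError(f"unknown model '{name}' for table_report")
    label = name.upper() + ("" if selection is None else f" on {selection.method}")
    return CVReport(label, chosen, cal_acc, pred_acc)


# ---------------------------------------------------------------------------
# Selection quality against planted ground truth
# ---------------------------------------------------------------------------


def _truth_bands(ground_truth: np.ndarray) -> list[np.ndarray]:
    gt = np.unique(np.asarray(ground_truth, dtype=int))
    if gt.size == 0:
        raise ValidationError("ground truth is empty")
    splits = np.flatnonzero(np.diff(gt) > 1) + 1
    return np.split(gt, splits)


def selection_quality(
    selection: SelectionResult,
    ground_truth: np.ndarray,
    tolerance: int = 2,
) -> SelectionQuality:
    """Band recall and index precision of a selection.

    Recall is the fraction of contiguous ground-truth bands hit by at least
    one selected index (within ``tolerance`` grid points); precision the
    fraction of selected indices within ``tolerance`` of any truth index.
    An empty selection reports 0/0 with the ``empty_selection`` flag set.
    """
    bands = _truth_bands(ground_truth)
    sel = selection.indices
    if sel.size == 0:
        return SelectionQuality(0.0, 0.0, 0, empty_selection=True)
    gt = np.unique(np.asarray(ground_truth, dtype=int))
    hit_bands = sum(
        1
        for band in bands
        if np.any((sel >= band.min() - tolerance) & (sel <= band.max() + tolerance))
    )
    near = np.min(np.abs(sel[:, None] - gt[None, :]), axis=1) <= tolerance
    return SelectionQuality(
        recall=hit_bands / len(bands),
        precision=float(np.mean(near)),
        n_selected=int(sel.size),
    )


# ---------------------------------------------------------------------------
# t-SNE wrapper (visualization only)
# ---------------------------------------------------------------------------


def tsne_embed(
    features: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding of feature rows (perplexity capped below N/3)."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    n = F.shape[0]
    if n < 4:
        raise ValidationError(f"t-SNE needs at least 4 samples, got {n}")
    perp = min(float(perplexity), (n - 1) / 3.0)
    coords = TSNE(
        n_components=2, perplexity=perp, random_state=seed, init="pca"
    ).fit_transform(F)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("t-SNE produced non-finite coordinates")
    return coords
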