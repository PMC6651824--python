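"""Spectral dataset container, delimited-text I/O, fold assignment and scaling.

The central object is :class:`SpectralDataset`: an absorbance matrix
(samples x wavenumbers) together with a strictly descending wavenumber axis
in cm^-1 (4000 -> 550 by convention, mirroring how mid-infrared spectra are
plotted) and integer class labels.  Everything downstream — auto-encoder
training, saliency selection, the chemometric baselines — consumes this one
container.

Datasets are serialized as plain CSV: one header row of wavenumbers plus a
``label`` column, one sample per row.  Gzip-compressed files are handled
transparently by pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SpectralDataset",
    "FoldAssignment",
    "ScalingRecord",
    "read_dataset",
    "write_dataset",
    "make_folds",
    "scale_to_unit_interval",
]


class ValidationError(ValueError):
    """A dataset, fold or configuration invariant was violated."""


@dataclass
class SpectralDataset:
    """Absorbance spectra with a common wavenumber axis and class labels.

    Parameters
    ----------
    wavenumbers:
        Strictly descending axis in cm^-1, length ``P``.
    absorbance:
        ``N x P`` matrix of unitless absorbance values (finite).
    labels:
        Length-``N`` integer class ids in ``0..C-1``; every class occupied.
    class_names:
        ``C`` display names, one per class.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if not self.class_names:
            n_cls = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = tuple(f"class_{i}" for i in range(n_cls))
        else:
            self.class_names = tuple(str(c) for c in self.class_names)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        wn, X, y = self.wavenumbers, self.absorbance, self.labels
        if X.ndim != 2:
            raise ValidationError(f"absorbance must be 2-D, got shape {X.shape}")
        n, p = X.shape
        if n < 2 or p < 2:
            raise ValidationError(f"need N >= 2 and P >= 2, got N={n}, P={p}")
        if wn.shape != (p,):
            raise ValidationError(
                f"wavenumber axis length {wn.size} != number of columns {p}"
            )
        d = np.diff(wn)
        if np.any(d == 0):
            raise ValidationError("duplicate wavenumbers in axis")
        if not np.all(d < 0):
            raise ValidationError("wavenumber axis must be strictly descending")
        if not np.all(np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise ValidationError(f"non-finite absorbance at row {i}, column {j}")
        if y.shape != (n,):
            raise ValidationError(f"labels length {y.size} != N={n}")
        c = len(self.class_names)
        if y.min(initial=0) < 0 or y.max(initial=0) >= c:
            bad = y[(y < 0) | (y >= c)][0]
            raise ValidationError(f"label {bad} outside 0..{c - 1}")
        present = np.bincount(y, minlength=c)
        if np.any(present == 0):
            missing = int(np.argmin(present))
            raise ValidationError(f"class {missing} has no samples")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def restrict(self, indices: Sequence[int]) -> "SpectralDataset":
        """Return a copy restricted to the given wavenumber columns."""
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_wavenumbers):
            raise ValidationError("selection index outside the wavenumber axis")
        return replace(
            self,
            wavenumbers=self.wavenumbers[idx],
            absorbance=self.absorbance[:, idx],
        )

    def subset_rows(self, rows: Sequence[int]) -> "SpectralDataset":
        rows = np.asarray(rows, dtype=int)
        return SpectralDataset(
            self.wavenumbers,
            self.absorbance[rows],
            self.labels[rows],
            self.class_names,
        )


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic stratified fold labels for cross validation."""

    fold_of_sample: np.ndarray
    n_folds: int
    seed: int

    def calibration_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)

    def prediction_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)


def make_folds(labels: np.ndarray, n_folds: int, seed: int) -> FoldAssignment:
    """Stratified fold assignment: within every class, fold sizes differ by <= 1.

    Samples of each class are shuffled with a seeded generator and dealt
    round-robin to the folds, so the assignment is reproducible for a fixed
    ``(labels, n_folds, seed)``.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    fold = np.full(labels.size, -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ValidationError(
                f"class {cls} has {idx.size} samples, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return FoldAssignment(fold_of_sample=fold, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

LABEL_COLUMN = "label"


def read_dataset(
    path: str | Path,
    label_column: str = LABEL_COLUMN,
    class_names: Sequence[str] | None = None,
) -> SpectralDataset:
    """Read a CSV spectral dataset (wavenumber header + one ``label`` column).

    The axis is reordered to descending regardless of the order in the file.
    Malformed numeric cells raise a parse error naming row and column;
    duplicate wavenumbers or non-finite absorbance raise ``ValidationError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise ValidationError(f"no '{label_column}' column in {path.name}")
    labels_raw = frame.pop(label_column)
    try:
        wn = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise ValidationError(f"non-numeric wavenumber header: {exc}") from exc
    if np.unique(wn).size != wn.size:
        raise ValidationError("duplicate wavenumbers in header")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"malformed numeric cell at row {i}, column '{frame.columns[j]}'"
        )
    X = numeric.to_numpy(dtype=float)
    try:
        y = labels_raw.astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"labels must be integers: {exc}") from exc
    if class_names is not None and y.size and y.max() >= len(class_names):
        raise ValidationError(
            f"label {int(y.max())} inconsistent with {len(class_names)} declared classes"
        )

    order = np.argsort(-wn, kind="stable")
    return SpectralDataset(wn[order], X[:, order], y, tuple(class_names or ()))


def write_dataset(dataset: SpectralDataset, path: str | Path) -> Path:
    """Write a dataset as CSV; ``read_dataset`` round-trips it to <= 1e-12."""
    dataset.validate()
    path = Path(path)
    cols = {f"{w:.10f}".rstrip("0").rstrip("."): dataset.absorbance[:, i]
            for i, w in enumerate(dataset.wavenumbers)}
    frame = pd.DataFrame(cols)
    frame[LABEL_COLUMN] = dataset.labels
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Scaling to the sigmoid-reconstructable range
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingRecord:
    """Per-column affine map of absorbance into ``[lo, hi]`` and its inverse.

    Needed because a sigmoid decoder can only reconstruct values in (0, 1);
    the raw absorbance range is unbounded.  Constant columns are mapped to
    the interval midpoint and restored exactly on inversion.
    """

    col_min: np.ndarray
    col_max: np.ndarray
    lo: float
    hi: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        safe = np.where(span == 0, 1.0, span)
        scaled = self.lo + (X - self.col_min) / safe * (self.hi - self.lo)
        mid = 0.5 * (self.lo + self.hi)
        return np.where(span == 0, mid, scaled)

    def invert(self, X_scaled: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        raw = self.col_min + (X_scaled - self.lo) / (self.hi - self.lo) * span
        return np.where(span == 0, self.col_min, raw)


def scale_to_unit_interval(
    dataset: SpectralDataset, lo: float = 0.05, hi: float = 0.95
) -> tuple[SpectralDataset, ScalingRecord]:
    """Affinely map every wavenumber column of ``dataset`` into ``[lo, hi]``."""
    if not (0 < lo < hi < 1):
        raise ValidationError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    X = dataset.absorbance
    record = ScalingRecord(X.min(axis=0), X.max(axis=0), float(lo), float(hi))
    scaled = replace(dataset, absorbance=record.apply(X))
    return scaled, record
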