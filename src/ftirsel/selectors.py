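"""Chemometric baseline selectors: PCA-loading and CARS over a PLS core.

PCA-loading scores every wavenumber by the largest absolute loading it
carries in the first few principal components of the (mean-centered)
absorbance matrix, and keeps the top-scoring local maxima of that curve —
the classic unsupervised way of reading "important bands" off a PCA.

CARS (competitive adaptive reweighted sampling) eliminates variables
iteratively: each Monte-Carlo run fits a PLS model on a row subsample,
ranks surviving variables by regression-coefficient magnitude, truncates to
an exponentially decaying retention count, randomly resamples variables in
proportion to their weights, and scores the surviving set by cross-validated
RMSE.  The run with the lowest RMSECV wins.  Class labels are handled by
casting classification as one-hot multi-response PLS regression.

The PLS core is a SIMPLS implementation written here (cross-checked against
an independent NIPALS implementation in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from sklearn.decomposition import PCA

from .dataset import ValidationError
from .saliency import SelectionResult, _local_extrema_mask

__all__ = [
    "PCAResult",
    "PLSModel",
    "CARSConfig",
    "pca_fit",
    "pca_loading_select",
    "pls_fit",
    "rmsecv",
    "edf_schedule",
    "cars_select",
]


# ---------------------------------------------------------------------------
# PCA loading selection
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Principal axes (rows), explained variance ratios and the column means."""

    loadings: np.ndarray  # (components, variables), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int
    mean: np.ndarray


def pca_fit(X: np.ndarray, n_components: int) -> PCAResult:
    """Column-centered PCA with unit-norm principal axes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    max_c = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_c):
        raise ValidationError(
            f"n_components must lie in 1..{max_c}, got {n_components}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    return PCAResult(
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        n_components=n_components,
        mean=model.mean_,
    )


def pca_loading_select(
    X: np.ndarray,
    n_pcs: int = 6,
    n_select: int = 39,
    wavenumbers: np.ndarray | None = None,
) -> SelectionResult:
    """Select the ``n_select`` variables with the largest PCA loadings.

    Each variable is scored by its maximum |loading| over the first
    ``n_pcs`` components; candidates are restricted to local maxima of the
    score curve (a band contributes its apex, not every grid point).  Ties
    break toward the higher wavenumber, i.e. the lower column index on the
    descending axis.  If fewer local maxima exist than requested, the
    restriction is dropped and a note records the fallback.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not (1 <= n_select <= X.shape[1]):
        raise ValidationError(f"n_select must lie in 1..{X.shape[1]}")
    pca = pca_fit(X, n_pcs)
    score = np.max(np.abs(pca.loadings), axis=0)

    note = None
    candidates = np.flatnonzero(_local_extrema_mask(score))
    if candidates.size < n_select:
        note = (
            f"only {candidates.size} local maxima for n_select={n_select}; "
            "fell back to global top-n without the extremum restriction"
        )
        candidates = np.arange(score.size)
    # stable sort on -score: equal scores keep ascending index order,
    # which on a descending axis is the higher wavenumber first
    order = candidates[np.argsort(-score[candidates], kind="stable")]
    idx = np.sort(order[:n_select])
    wn = None
    if wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float).ravel()[idx]
    return SelectionResult(
        method="pca-loading", indices=idx, wavenumbers=wn, count=n_select, note=note
    )


# ---------------------------------------------------------------------------
# PLS (SIMPLS) and RMSECV
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Fitted PLS regression: ``predict(X) = (X - x_mean) @ coef + y_mean``."""

    coef: np.ndarray  # (variables, responses)
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def pls_fit(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSModel:
    """SIMPLS partial least squares regression on centered X and Y.

    Latent directions maximize covariance with the response under
    orthogonality of successive score vectors (de Jong's SIMPLS deflation
    of the cross-product matrix).  ``Y`` may be a one-hot class encoding,
    which is how the classification problem is fed to CARS.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValidationError("X and Y row counts differ")
    if np.allclose(Y.var(axis=0), 0):
        raise ValidationError("response has zero variance")
    max_c = min(n - 1, p)
    if not (1 <= n_components <= max_c):
        raise ValidationError(f"n_components must lie in 1..{max_c}")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = X - x_mean
    Y0 = Y - y_mean

    S = X0.T @ Y0  # (p, q) cross-product
    R = np.zeros((p, n_components))  # X weights (applied to raw centered X)
    Q = np.zeros((Y.shape[1], n_components))  # Y loadings
    V = np.zeros((p, n_components))  # orthonormal basis of X loadings
    for a in range(n_components):
        # dominant right singular vector of the deflated cross-product
        _, _, vt = np.linalg.svd(S, full_matrices=False)
        q = vt[0]
        r = S @ q
        t = X0 @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise ValidationError(
                f"rank deficiency at component {a + 1}; lower n_components"
            )
        t /= normt
        r /= normt
        p_load = X0.T @ t
        q_load = Y0.T @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        S -= np.outer(v, v @ S)
        R[:, a], Q[:, a], V[:, a] = r, q_load, v

    coef = R @ Q.T
    return PLSModel(coef=coef, x_mean=x_mean, y_mean=y_mean, n_components=n_components)


def rmsecv(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated RMSE of PLS predictions, pooled over samples and responses."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValidationError(f"n_folds must lie in 2..{n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)

    sq_sum, count = 0.0, 0
    for held in folds:
        train = np.setdiff1d(order, held)
        max_c = min(train.size - 1, X.shape[1])
        if n_components > max_c:
            raise ValidationError(
                f"n_components={n_components} infeasible for a training fold "
                f"of {train.size} samples and {X.shape[1]} variables"
            )
        model = pls_fit(X[train], Y[train], n_components)
        resid = model.predict(X[held]) - Y[held]
        sq_sum += float(np.sum(resid**2))
        count += resid.size
    return float(np.sqrt(sq_sum / count))


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------


@dataclass
class CARSConfig:
    """Monte-Carlo settings for competitive adaptive reweighted sampling."""

    n_runs: int = 50
    n_folds: int = 5
    max_components: int = 10
    sample_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValidationError("n_runs must be >= 2")
        if not (0 < self.sample_fraction <= 1):
            raise ValidationError("sample_fraction must lie in (0, 1]")
        if self.max_components < 1:
            raise ValidationError("max_components must be >= 1")


def edf_schedule(n_runs: int, n_vars: int) -> np.ndarray:
    """Exponentially decaying retention ratios r_i = (P/2)^(-(i-1)/(N-1)).

    Calibrated so run 1 retains the whole axis (r = 1) and the final run
    retains 2 variables (r = 2/P) — the standard CARS schedule.
    """
    if n_runs < 2 or n_vars < 2:
        raise ValidationError("need n_runs >= 2 and n_vars >= 2")
    i = np.arange(1, n_runs + 1)
    return np.exp(-(i - 1) / (n_runs - 1) * np.log(n_vars / 2.0))


def _one_hot(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int).ravel()
    k = int(y.max()) + 1
    if k < 2:
        raise ValidationError("CARS needs at least 2 classes")
    return np.eye(k)[y]


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    config: CARSConfig | None = None,
    wavenumbers: np.ndarray | None = None,
) -> tuple[SelectionResult, dict]:
    """CARS variable selection over one-hot PLS regression.

    Per run: fit PLS on a Monte-Carlo row subsample restricted to the
    surviving variables; weight each variable by the L2 norm of its
    regression-coefficient row times the variable's standard deviation
    (standardized coefficient); keep the top variables per the exponential
    decay schedule, drawn without replacement in proportion to their
    weights; finally score the surviving set by RMSECV on the full
    calibration data.  Variables compete through the per-run Monte-Carlo
    subsample re-ranking the weights.  The surviving set of the
    minimum-RMSECV run is returned.

    Diagnostics carry per-run variable counts, the RMSECV trace, the
    schedule ratios and the index of the winning run.
    """
    config = config or CARSConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = _one_hot(y)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    ratios = edf_schedule(config.n_runs, p)

    survivors = np.arange(p)
    counts: list[int] = []
    traces: list[float] = []
    history: list[np.ndarray] = []
    n_cal = max(2, int(round(config.sample_fraction * n)))

    for i in range(config.n_runs):
        rows = rng.choice(n, size=min(n_cal, n), replace=False)
        ncomp = min(config.max_components, rows.size - 1, survivors.size)
        try:
            model = pls_fit(X[np.ix_(rows, survivors)], Y[rows], ncomp)
            # standardized coefficient magnitude: |b_j| * sd(x_j), so a
            # variable's weight reflects its contribution to the prediction
            # rather than its measurement scale (a near-constant variable
            # can carry a huge raw coefficient while contributing nothing)
            w = np.linalg.norm(model.coef, axis=1) * X[
                np.ix_(rows, survivors)
            ].std(axis=0)
        except ValidationError:
            w = np.ones(survivors.size)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = np.maximum(w, 1e-300)

        n_keep = min(max(2, int(round(ratios[i] * p))), survivors.size)
        top = np.argsort(-w, kind="stable")[:n_keep]
        cand, w_cand = survivors[top], w[top]
        # adaptive reweighted sampling: n_keep weighted draws without
        # replacement from the retained candidates — an exhaustive draw, so
        # the retained set follows the decay schedule exactly; the
        # competition between variables comes from the per-run Monte-Carlo
        # row subsample re-ranking the coefficient weights
        draws = rng.choice(cand, size=n_keep, replace=False,
                           p=w_cand / w_cand.sum())
        survivors = np.sort(draws)

        ncomp_cv = min(config.max_components, survivors.size)
        try:
            score = rmsecv(
                X[:, survivors], Y, ncomp_cv,
                n_folds=config.n_folds, seed=config.seed + i,
            )
        except ValidationError:
            score = np.inf  # infeasible run: excluded from the minimum
        counts.append(int(survivors.size))
        traces.append(score)
        history.append(survivors.copy())

    traces_arr = np.asarray(traces)
    if not np.any(np.isfinite(traces_arr)):
        raise ValidationError("every CARS run was infeasible")
    best = int(np.argmin(traces_arr))
    idx = history[best]
    wn = None
    if wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float).ravel()[idx]
    result = SelectionResult(
        method="cars", indices=idx, wavenumbers=wn, count=idx.size
    )
    diagnostics = {
        "counts": counts,
        "rmsecv": traces,
        "ratios": ratios,
        "best_run": best,
    }
    return result, diagnostics
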