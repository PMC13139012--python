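"""Centered PCA and NIPALS partial least squares regression.

PCA is computed by SVD of the mean-centered matrix and serves score-space
outlier screening and exploratory variance accounting.  PLSR uses the
NIPALS algorithm with deflation — components are extracted one at a time
as directions of maximal covariance between spectra and the reference
value — because each component can then be verified directly against its
defining recursion.  X is centered but not autoscaled: scale handling is
the job of the pretreatment chain.

Sign convention: for each component the loading (PCA) or weight (PLS)
element of largest magnitude is made positive, so decompositions are
reproducible across runs and platforms.

Model complexity (the latent-variable count) is chosen by k-fold
cross-validation with venetian-blind folds, taking the argmin of RMSECV
with ties broken toward the smaller count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np


class FactorModelError(ValueError):
    pass


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return signs


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centered principal component decomposition.

    ``loadings`` is p x k with orthonormal columns; ``score_variances``
    holds per-component score variances (ddof=1) and ``explained_ratio``
    their fractions of the total centered variance.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    score_variances: np.ndarray
    explained_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (centered) spectra onto the retained components."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_spectrum) @ self.loadings


def pca_fit(X: np.ndarray, k_max: int | None = None) -> PCAModel:
    """Fit centered PCA by SVD, components ordered by decreasing variance.

    ``k_max`` caps the number of retained components; it may not exceed
    ``min(n - 1, p)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 2:
        raise FactorModelError("PCA needs at least 2 samples")
    avail = min(n - 1, p)
    if k_max is None:
        k_max = avail
    if k_max < 1:
        raise FactorModelError("k_max must be >= 1")
    if k_max > avail:
        raise FactorModelError(f"k_max {k_max} exceeds min(n-1, p) = {avail}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = svals**2 / (n - 1)
    total = np.sum(Xc**2) / (n - 1)
    loadings = vt[:avail].T
    signs = _fix_sign(loadings)
    loadings = loadings * signs
    ratio = variances[:avail] / total if total > 0 else np.zeros(avail)
    return PCAModel(
        mean_spectrum=mean,
        loadings=loadings[:, :k_max],
        score_variances=variances[:k_max],
        explained_ratio=ratio[:k_max],
    )


def choose_k(model: PCAModel, threshold: float = 0.99) -> int:
    """Smallest component count whose cumulative explained variance
    reaches ``threshold``; capped at the available components."""
    if not 0 < threshold <= 1:
        raise FactorModelError("threshold must be in (0, 1]")
    cumulative = np.cumsum(model.explained_ratio)
    hits = np.flatnonzero(cumulative >= threshold - 1e-12)
    return int(hits[0]) + 1 if hits.size else model.n_components


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """NIPALS PLS1 regression model.

    The regression vector is assembled as ``B = W (P'W)^-1 q`` so that
    predictions are ``y_mean + (X - x_mean) @ B``.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x k (unit norm columns)
    x_loadings: np.ndarray   # p x k
    y_loadings: np.ndarray   # k
    regression_vector: np.ndarray  # p
    n_lv: int

    def to_json(self, path: str | Path) -> None:
        doc = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "n_lv": self.n_lv,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            x_mean=np.asarray(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            weights=np.asarray(doc["weights"], dtype=float),
            x_loadings=np.asarray(doc["x_loadings"], dtype=float),
            y_loadings=np.asarray(doc["y_loadings"], dtype=float),
            regression_vector=np.asarray(doc["regression_vector"], dtype=float),
            n_lv=int(doc["n_lv"]),
        )


def _nipals_components(
    Xc: np.ndarray, yc: np.ndarray, n_lv: int, on_rank_deficient: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract up to n_lv NIPALS components from centered data.

    For a univariate response the weight vector is available in closed
    form per component (w ∝ X'y), so no inner iteration is needed.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X_work = Xc.copy()
    y_work = yc.copy()
    x_scale = max(float(np.abs(Xc).max()), 1.0)
    extracted = 0
    for a in range(n_lv):
        w = X_work.T @ y_work
        wnorm = np.linalg.norm(w)
        if wnorm <= 1e-12 * x_scale * max(float(np.abs(yc).max()), 1.0):
            if on_rank_deficient == "truncate":
                break
            raise FactorModelError(
                f"rank deficiency at component {a + 1}: requested n_lv={n_lv}"
            )
        w /= wnorm
        t = X_work @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            if on_rank_deficient == "truncate":
                break
            raise FactorModelError(
                f"degenerate score at component {a + 1}: requested n_lv={n_lv}"
            )
        P[:, a] = X_work.T @ t / tt
        q[a] = float(y_work @ t) / tt
        W[:, a] = w
        X_work = X_work - np.outer(t, P[:, a])
        y_work = y_work - q[a] * t
        extracted += 1
    return W[:, :extracted], P[:, :extracted], q[:extracted]


def plsr_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    on_rank_deficient: str = "error",
) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    ``on_rank_deficient`` controls what happens when the requested count
    exceeds the data's effective rank: ``"error"`` (default) raises,
    ``"truncate"`` keeps the extractable components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise FactorModelError(f"y length {y.size} != {n} rows")
    if n_lv < 1:
        raise FactorModelError("n_lv must be >= 1")
    if n_lv >= n:
        raise FactorModelError(f"n_lv {n_lv} must be < n = {n}")
    if np.std(y) == 0:
        raise FactorModelError("y has zero variance")
    if on_rank_deficient not in ("error", "truncate"):
        raise FactorModelError("on_rank_deficient must be 'error' or 'truncate'")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_components(X - x_mean, y - y_mean, n_lv, on_rank_deficient)
    signs = _fix_sign(W)
    W, P, q = W * signs, P * signs, q * signs
    B = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=B,
        n_lv=W.shape[1],
    )


def plsr_predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict reference values: ``y_mean + (X_new - x_mean) @ B``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise FactorModelError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.regression_vector


def _regression_vectors_per_k(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Regression vector for every truncation 1..k of one NIPALS fit."""
    return [
        W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])
        for k in range(1, W.shape[1] + 1)
    ]


def venetian_blind_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Deterministic interleaved folds: fold j holds indices j, j+k, ..."""
    return [np.arange(j, n, n_folds) for j in range(n_folds)]


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    lv_grid: list[int] | range | None = None,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    shuffle: bool = False,
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by k-fold cross-validation.

    Folds are venetian blinds (deterministic) unless ``shuffle`` is set,
    in which case sample order is permuted with ``rng`` first.  Returns
    ``(n_lv, rmsecv)`` where ``rmsecv[i]`` corresponds to ``lv_grid[i]``;
    the argmin wins, ties go to the smaller count.  Grid entries that
    exceed a training fold's capacity are scored with the largest
    extractable component count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if lv_grid is None:
        lv_grid = range(1, 16)
    lv_grid = [int(k) for k in lv_grid]
    if not lv_grid or min(lv_grid) < 1:
        raise FactorModelError("lv_grid must contain positive counts")
    if n_folds < 2:
        raise FactorModelError("n_folds must be >= 2")
    if n < n_folds:
        raise FactorModelError(f"cannot make {n_folds} folds from {n} samples")
    order = np.arange(n)
    if shuffle:
        if rng is None:
            raise FactorModelError("shuffle=True requires an rng")
        order = rng.permutation(n)
    folds = venetian_blind_folds(n, n_folds)
    k_max = max(lv_grid)
    sq_errors = np.zeros(len(lv_grid))
    counts = np.zeros(len(lv_grid))
    for fold in folds:
        if fold.size == 0:
            raise FactorModelError("empty cross-validation fold")
        test_idx = order[fold]
        train_idx = np.setdiff1d(order, test_idx)
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        x_mean, y_mean = X_tr.mean(axis=0), float(y_tr.mean())
        limit = min(k_max, X_tr.shape[0] - 1)
        W, P, q = _nipals_components(X_tr - x_mean, y_tr - y_mean, limit, "truncate")
        per_k = _regression_vectors_per_k(W, P, q)
        Xc_te = X_te - x_mean
        for i, k in enumerate(lv_grid):
            B = per_k[min(k, len(per_k)) - 1]
            resid = y_te - (y_mean + Xc_te @ B)
            sq_errors[i] += float(resid @ resid)
            counts[i] += resid.size
    rmsecv = np.sqrt(sq_errors / counts)
    best = int(np.argmin(rmsecv))  # np.argmin returns the first (smallest-k) minimum
    return lv_grid[best], rmsecv
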