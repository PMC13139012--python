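"""Two-stage outlier screening: PCA-Mahalanobis distance, then
concentration residuals.

Spectral outliers (acquisition faults) are flagged by their squared
Mahalanobis distance in truncated PCA score space; the cutoff is the
chi-square quantile at the configured confidence with k degrees of
freedom — the large-n reading of a "confidence ellipse limit" on scores.
A Hotelling T2 (F-distribution) cutoff is available behind a flag for
small-n work.

Chemical outliers (wet-chemistry or transcription faults) are flagged by
the cross-validated residuals of a PLSR of the reference value on the
pretreated spectra: samples whose absolute out-of-fold residual exceeds
``c`` times the sample SD of the residuals are removed.  Out-of-fold
residuals are used because a training-set residual shrinks toward zero
exactly for the anomalous samples the screen is meant to find — a
flexible latent-variable model fitted on all rows can absorb a shifted
reference value.  Screening is single-pass — one removal round per
criterion, spectral first, chemical on the spectral survivors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .factormodels import (
    choose_k,
    pca_fit,
    plsr_fit,
    plsr_predict,
    select_lv,
    venetian_blind_folds,
    _nipals_components,
)
from .pretreat import PreprocessChain, parse_chain
from .specio import SpectralDataset


class ScreenError(ValueError):
    pass


def _default_screening_chains() -> dict[str, str]:
    # per-state pretreatment ahead of the screening PCA: intact kernels
    # respond best to vector normalization, granules to MSC
    return {
        "in_shell": "Normalize",
        "de_shelled": "Normalize",
        "granules": "MSC",
        "unknown": "Normalize",
    }


@dataclass
class ScreeningConfig:
    """Parameters of the two-stage screen.

    ``fixed_k`` pins the score-space dimension (default 4, the count
    whose cumulative explained variance typically exceeds the
    ``pc_threshold`` on this data class); set it to ``None`` to derive k
    from ``pc_threshold`` per dataset.
    """

    screening_preprocess: dict[str, str] = field(default_factory=_default_screening_chains)
    fixed_k: int | None = 4
    pc_threshold: float = 0.99
    md_confidence: float = 0.95
    residual_multiplier: float = 2.5
    residual_model_lv: int | str = "cv"
    threshold_family: str = "chi2"  # or "hotelling"

    def __post_init__(self) -> None:
        if not 0 < self.md_confidence < 1:
            raise ScreenError("md_confidence must be in (0, 1)")
        if self.residual_multiplier <= 0:
            raise ScreenError("residual_multiplier must be > 0")
        if self.threshold_family not in ("chi2", "hotelling"):
            raise ScreenError("threshold_family must be 'chi2' or 'hotelling'")

    def chain_for(self, state: str) -> PreprocessChain:
        name = self.screening_preprocess.get(state, "Normalize")
        return parse_chain(name)


@dataclass
class OutlierReport:
    """Everything needed to audit one screening run."""

    spectral_outlier_ids: list[int]
    chemical_outlier_ids: list[int]
    md_squared: dict[int, float]
    md_threshold: float
    residuals: dict[int, float]
    residual_sd: float
    removed_ids: list[int]
    k_components: int
    residual_n_lv: int

    def to_json(self, path: str | Path, config: ScreeningConfig | None = None) -> None:
        doc = {
            "spectral_outlier_ids": self.spectral_outlier_ids,
            "chemical_outlier_ids": self.chemical_outlier_ids,
            "md_squared": {str(k): v for k, v in self.md_squared.items()},
            "md_threshold": self.md_threshold,
            "residuals": {str(k): v for k, v in self.residuals.items()},
            "residual_sd": self.residual_sd,
            "removed_ids": self.removed_ids,
            "k_components": self.k_components,
            "residual_n_lv": self.residual_n_lv,
        }
        if config is not None:
            doc["config"] = {
                "screening_preprocess": config.screening_preprocess,
                "fixed_k": config.fixed_k,
                "pc_threshold": config.pc_threshold,
                "md_confidence": config.md_confidence,
                "residual_multiplier": config.residual_multiplier,
                "residual_model_lv": config.residual_model_lv,
                "threshold_family": config.threshold_family,
            }
        Path(path).write_text(json.dumps(doc, indent=2))


def mahalanobis_sq(scores: np.ndarray, score_variances: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of centered scores.

    ``MD2_i = sum_k t_ik^2 / var_k``; on exactly centered scores with
    ddof=1 variances the distances satisfy ``sum_i MD2_i = (n-1) k``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    var = np.asarray(score_variances, dtype=float)
    if var.size != scores.shape[1]:
        raise ScreenError(f"{var.size} variances for {scores.shape[1]} score columns")
    if np.any(var <= 0):
        raise ScreenError("score variances must all be > 0 (degenerate component)")
    return np.sum(scores**2 / var, axis=1)


def md_threshold(confidence: float, k: int, n: int, family: str = "chi2") -> float:
    """Cutoff on MD2 for the given confidence ellipse.

    ``chi2``: the chi-square quantile with k df (large-n ellipse).
    ``hotelling``: the Hotelling T2 limit k(n-1)(n+1)/(n(n-k)) F_{k,n-k}.
    """
    if family == "chi2":
        return float(stats.chi2.ppf(confidence, df=k))
    if family == "hotelling":
        scale = k * (n - 1) * (n + 1) / (n * (n - k))
        return float(scale * stats.f.ppf(confidence, k, n - k))
    raise ScreenError(f"unknown threshold family {family!r}")


def spectral_outliers(
    dataset: SpectralDataset, cfg: ScreeningConfig
) -> tuple[list[int], dict]:
    """Flag samples beyond the confidence ellipse in PCA score space.

    The state's screening pretreatment is applied, PCA fitted on the full
    matrix, k components retained (``fixed_k`` or the cumulative-variance
    rule) and samples with ``MD2`` above the threshold flagged.
    """
    chain = cfg.chain_for(dataset.state)
    X = chain.fit(dataset.absorbance, dataset.wavelengths).transform(
        dataset.absorbance, dataset.wavelengths
    )
    n = X.shape[0]
    avail = min(n - 1, X.shape[1])
    model = pca_fit(X, k_max=min(max(cfg.fixed_k or 6, 6), avail))
    if cfg.fixed_k is not None:
        k = min(cfg.fixed_k, model.n_components)
    else:
        k = choose_k(model, cfg.pc_threshold)
    if n <= k:
        raise ScreenError(f"need n > k; got n={n}, k={k}")
    scores = model.transform(X)[:, :k]
    md2 = mahalanobis_sq(scores, model.score_variances[:k])
    threshold = md_threshold(cfg.md_confidence, k, n, cfg.threshold_family)
    flagged = [int(s) for s, d in zip(dataset.sample_ids, md2) if d > threshold]
    diagnostics = {
        "md_squared": {int(s): float(d) for s, d in zip(dataset.sample_ids, md2)},
        "threshold": threshold,
        "k": k,
        "explained_ratio": model.explained_ratio[:k].tolist(),
        "chain": chain.name,
    }
    return flagged, diagnostics


def _cv_residuals(X: np.ndarray, y: np.ndarray, n_lv: int, n_folds: int) -> np.ndarray:
    """Out-of-fold PLSR residuals at a fixed latent-variable count."""
    n = X.shape[0]
    residuals = np.empty(n)
    for fold in venetian_blind_folds(n, n_folds):
        train = np.setdiff1d(np.arange(n), fold)
        x_mean, y_mean = X[train].mean(axis=0), float(y[train].mean())
        limit = min(n_lv, train.size - 1)
        W, P, q = _nipals_components(
            X[train] - x_mean, y[train] - y_mean, limit, "truncate"
        )
        B = W @ np.linalg.solve(P.T @ W, q)
        residuals[fold] = y[fold] - (y_mean + (X[fold] - x_mean) @ B)
    return residuals


def chemical_outliers(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: np.ndarray,
    cfg: ScreeningConfig,
    wavelengths: np.ndarray | None = None,
    state: str = "unknown",
) -> tuple[list[int], dict]:
    """Flag samples with anomalous reference values.

    The state's screening pretreatment is applied (when a wavelength grid
    is given), the latent-variable count is chosen by cross-validation
    (unless pinned by ``residual_model_lv``), and each sample's residual
    is its out-of-fold prediction error at that count.  Samples whose
    absolute residual exceeds ``residual_multiplier`` times the residual
    sample SD (ddof=1) are flagged in a single pass.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    ids = np.asarray(sample_ids, dtype=int)
    n = X.shape[0]
    if n < 10:
        raise ScreenError(f"chemical screening needs n >= 10, got {n}")
    if wavelengths is not None:
        chain = cfg.chain_for(state)
        X = chain.fit(X, wavelengths).transform(X, wavelengths)
    n_folds = min(5, n)
    if cfg.residual_model_lv == "cv":
        grid = range(1, min(15, n - 2) + 1)
        n_lv, _ = select_lv(X, y, lv_grid=grid, n_folds=n_folds)
    else:
        n_lv = int(cfg.residual_model_lv)
    residuals = _cv_residuals(X, y, n_lv, n_folds)
    sd = float(np.std(residuals, ddof=1))
    cutoff = cfg.residual_multiplier * sd
    # residuals at numerical-noise scale carry no outlier information
    floor = 1e-8 * max(1.0, float(np.std(y, ddof=1)))
    if sd < floor:
        flagged: list[int] = []
    else:
        flagged = [int(s) for s, r in zip(ids, residuals) if abs(r) > cutoff]
    diagnostics = {
        "residuals": {int(s): float(r) for s, r in zip(ids, residuals)},
        "residual_sd": sd,
        "cutoff": cutoff,
        "n_lv": n_lv,
        "residual_basis": "cross_validated",
    }
    return flagged, diagnostics


def screen_dataset(
    dataset: SpectralDataset, cfg: ScreeningConfig | None = None
) -> tuple[SpectralDataset, OutlierReport]:
    """Run the full two-stage screen and return survivors plus a report.

    Spectral screening runs first on the whole dataset; chemical
    screening runs on the spectral survivors; the union is removed.
    """
    if cfg is None:
        cfg = ScreeningConfig()
    if dataset.reference is None:
        raise ScreenError("screening needs reference values")
    spec_ids, spec_diag = spectral_outliers(dataset, cfg)
    survivors = dataset.drop(spec_ids)
    chem_ids, chem_diag = chemical_outliers(
        survivors.absorbance,
        survivors.reference,
        survivors.sample_ids,
        cfg,
        wavelengths=survivors.wavelengths,
        state=survivors.state,
    )
    removed = sorted(set(spec_ids) | set(chem_ids))
    clean = dataset.drop(removed)
    if clean.n_samples == 0:
        raise ScreenError("screening removed every sample")
    report = OutlierReport(
        spectral_outlier_ids=sorted(spec_ids),
        chemical_outlier_ids=sorted(chem_ids),
        md_squared=spec_diag["md_squared"],
        md_threshold=spec_diag["threshold"],
        residuals=chem_diag["residuals"],
        residual_sd=chem_diag["residual_sd"],
        removed_ids=removed,
        k_components=spec_diag["k"],
        residual_n_lv=chem_diag["n_lv"],
    )
    return clean, report
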