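"""Full calibration workflow: screen, split, pretreatment x PLSR grid.

For each physical state the pipeline generates (or loads) a dataset,
removes outliers, partitions it with SPXY, and then, for every
pretreatment chain in the grid: fits the chain on the calibration set,
selects the latent-variable count by cross-validation on the calibration
set only, fits the PLSR and evaluates

    R2c / RMSEC   on the calibration set,
    R2p / RMSEP   on the prediction set,
    RPD = SD(y_pred_set) / RMSEP,
    RER = range(y_pred_set) / RMSEP.

The best model per state maximizes R2p, ties broken by lower RMSEP.
Prediction-set rows never influence pretreatment fitting, latent-variable
selection or model coefficients.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .factormodels import PLSRModel, plsr_fit, plsr_predict, select_lv
from .pretreat import CHAIN_NAMES, parse_chain
from .screen import OutlierReport, ScreeningConfig, screen_dataset
from .simkernel import GeneratorConfig, StateParams, generate_dataset
from .specio import STATES, SpectralDataset, read_csv_dataset
from .spxy import SplitResult, split_dataset


class CalibrateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST (not squared correlation)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise CalibrateError("length mismatch")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise CalibrateError("constant y: R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error with divisor n."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise CalibrateError("empty vectors")
    if y.size != yhat.size:
        raise CalibrateError("length mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y_prediction_set: np.ndarray, rmsep: float) -> float:
    """Residual predictive deviation: SD(y, ddof=1) / RMSEP."""
    y = np.asarray(y_prediction_set, dtype=float).ravel()
    if y.size < 2:
        raise CalibrateError("RPD needs at least 2 prediction samples")
    if rmsep <= 0:
        raise CalibrateError("RPD undefined for RMSEP <= 0")
    return float(np.std(y, ddof=1)) / rmsep


def rer(y_prediction_set: np.ndarray, rmsep: float) -> float:
    """Range error ratio: (max(y) - min(y)) / RMSEP."""
    y = np.asarray(y_prediction_set, dtype=float).ravel()
    if y.size == 0:
        raise CalibrateError("empty prediction set")
    if rmsep <= 0:
        raise CalibrateError("RER undefined for RMSEP <= 0")
    return float(y.max() - y.min()) / rmsep


@dataclass
class ModelMetrics:
    """One row of the model grid (one state x pretreatment cell)."""

    state: str
    chain: str
    n_lv: int
    r2c: float
    rmsec: float
    r2p: float
    rmsep: float
    rpd: float
    rer: float
    error: str | None = None

    def as_row(self) -> dict:
        return {
            "state": self.state,
            "chain": self.chain,
            "n_LV": self.n_lv,
            "R2c": self.r2c,
            "RMSEC": self.rmsec,
            "R2p": self.r2p,
            "RMSEP": self.rmsep,
            "RPD": self.rpd,
            "RER": self.rer,
            "error": self.error or "",
        }


def evaluate_model(
    model: PLSRModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    state: str = "unknown",
    chain: str = "Original",
) -> ModelMetrics:
    """Fill the full metric set for a fitted model.

    A perfect prediction set (RMSEP = 0) reports ``inf`` for RPD and RER
    rather than raising, so degenerate noiseless fixtures remain
    representable.
    """
    yhat_cal = plsr_predict(model, X_cal)
    yhat_pred = plsr_predict(model, X_pred)
    rmsec = rmse(y_cal, yhat_cal)
    rmsep = rmse(y_pred, yhat_pred)
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    # an RMSEP at numerical-noise scale means a (degenerate) perfect fit
    floor = 1e-10 * max(1.0, float(np.abs(y_pred).max()))
    if rmsep > floor:
        rpd_val = rpd(y_pred, rmsep)
        rer_val = rer(y_pred, rmsep)
    else:
        rpd_val = math.inf
        rer_val = math.inf
    return ModelMetrics(
        state=state,
        chain=chain,
        n_lv=model.n_lv,
        r2c=r_squared(y_cal, yhat_cal),
        rmsec=rmsec,
        r2p=r_squared(y_pred, yhat_pred),
        rmsep=rmsep,
        rpd=rpd_val,
        rer=rer_val,
    )


# ---------------------------------------------------------------------------
# the model grid
# ---------------------------------------------------------------------------

@dataclass
class LVConfig:
    """Latent-variable selection settings (cross-validation on the
    calibration set)."""

    grid_max: int = 15
    n_folds: int = 5


@dataclass
class GridResult:
    """All metric rows for one state plus the winning cell."""

    rows: list[ModelMetrics]
    best: ModelMetrics | None
    state: str

    def row(self, chain: str) -> ModelMetrics:
        for r in self.rows:
            if r.chain == chain:
                return r
        raise KeyError(chain)


def _best_row(rows: list[ModelMetrics]) -> ModelMetrics | None:
    ok = [r for r in rows if r.error is None]
    if not ok:
        return None
    return max(ok, key=lambda r: (r.r2p, -r.rmsep))


def run_grid(
    dataset: SpectralDataset,
    split: SplitResult,
    chains: tuple[str, ...] | list[str] = CHAIN_NAMES,
    lv_config: LVConfig | None = None,
) -> GridResult:
    """Fit and evaluate one PLSR per pretreatment chain.

    Pretreatment fitting (MSC reference) and latent-variable selection
    see calibration rows only.  A failing chain produces a row carrying
    its error message instead of aborting the grid.
    """
    if lv_config is None:
        lv_config = LVConfig()
    if dataset.reference is None:
        raise CalibrateError("grid needs reference values")
    cal = dataset.subset(split.calibration_ids)
    pred = dataset.subset(split.prediction_ids)
    rows: list[ModelMetrics] = []
    for name in chains:
        try:
            chain = parse_chain(name)
            X_cal, X_pred = chain.fit_transform(
                cal.absorbance, pred.absorbance, dataset.wavelengths
            )
            grid = range(1, min(lv_config.grid_max, cal.n_samples - 2) + 1)
            n_lv, _ = select_lv(
                X_cal, cal.reference, lv_grid=grid, n_folds=lv_config.n_folds
            )
            model = plsr_fit(X_cal, cal.reference, n_lv, on_rank_deficient="truncate")
            rows.append(
                evaluate_model(
                    model,
                    X_cal,
                    cal.reference,
                    X_pred,
                    pred.reference,
                    state=dataset.state,
                    chain=name,
                )
            )
        except Exception as exc:  # failed cells are reported, not fatal
            rows.append(
                ModelMetrics(
                    state=dataset.state, chain=name, n_lv=0,
                    r2c=math.nan, rmsec=math.nan, r2p=math.nan,
                    rmsep=math.nan, rpd=math.nan, rer=math.nan,
                    error=str(exc),
                )
            )
    return GridResult(rows=rows, best=_best_row(rows), state=dataset.state)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------

def _default_outlier_counts() -> dict[str, tuple[int, int]]:
    # (spectral, chemical) planted per state: intact in-shell kernels are
    # the most fault-prone presentation, granules the least
    return {"in_shell": (4, 4), "de_shelled": (3, 4), "granules": (2, 3)}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_files: dict[str, str] | None = None  # state -> CSV path; overrides generator
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    split_fraction: float = 0.75
    chains: tuple[str, ...] = CHAIN_NAMES
    lv: LVConfig = field(default_factory=LVConfig)
    states: tuple[str, ...] = STATES
    outlier_counts: dict[str, tuple[int, int]] = field(default_factory=_default_outlier_counts)
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {
            "generator", "input_files", "screening", "split_fraction",
            "chains", "lv", "states", "outlier_counts", "seed", "output_dir",
        }
        unknown = set(doc) - known
        if unknown:
            raise CalibrateError(f"unknown config keys: {sorted(unknown)}")
        gen_doc = dict(doc.get("generator") or {})
        if "state_params" in gen_doc:
            gen_doc["state_params"] = {
                state: StateParams(**params)
                for state, params in gen_doc["state_params"].items()
            }
        screening_doc = dict(doc.get("screening") or {})
        lv_doc = dict(doc.get("lv") or {})
        counts = {
            state: tuple(v)
            for state, v in (doc.get("outlier_counts") or _default_outlier_counts()).items()
        }
        cfg = cls(
            generator=GeneratorConfig(**gen_doc),
            input_files=doc.get("input_files"),
            screening=ScreeningConfig(**screening_doc),
            split_fraction=float(doc.get("split_fraction", 0.75)),
            chains=tuple(doc.get("chains", CHAIN_NAMES)),
            lv=LVConfig(**lv_doc),
            states=tuple(doc.get("states", STATES)),
            outlier_counts=counts,
            seed=int(doc.get("seed", 0)),
            output_dir=doc.get("output_dir"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise CalibrateError("split_fraction must be in (0, 1)")
        for name in self.chains:
            parse_chain(name)  # raises on unknown names
        for state in self.states:
            if state not in STATES:
                raise CalibrateError(f"unknown state {state!r}")


@dataclass
class StateResult:
    """Per-state pipeline products."""

    state: str
    dataset: SpectralDataset
    report: OutlierReport
    split: SplitResult
    grid: GridResult


def _state_generator_config(config: PipelineConfig, state: str, seed: int) -> GeneratorConfig:
    base = config.generator
    n_spec, n_chem = config.outlier_counts.get(
        state, (base.n_spectral_outliers, base.n_chemical_outliers)
    )
    fields = {k: getattr(base, k) for k in base.__dataclass_fields__}
    fields.update(n_spectral_outliers=n_spec, n_chemical_outliers=n_chem, seed=seed)
    return GeneratorConfig(**fields)


def run_pipeline(config: PipelineConfig) -> dict[str, StateResult]:
    """Run generate/load -> screen -> SPXY split -> model grid per state.

    All randomness derives from ``config.seed``; per-state generator
    seeds are offset by the state's index so the three datasets are
    independent but jointly reproducible.  When ``output_dir`` is set the
    standard artifact files are written there.
    """
    config.validate()
    results: dict[str, StateResult] = {}
    for i, state in enumerate(config.states):
        if config.input_files and state in config.input_files:
            dataset = read_csv_dataset(config.input_files[state])
        else:
            gen_cfg = _state_generator_config(config, state, config.seed + 1000 * i)
            dataset, _ = generate_dataset(gen_cfg, state)
        clean, report = screen_dataset(dataset, config.screening)
        split, _, _ = split_dataset(clean, config.split_fraction)
        grid = run_grid(clean, split, config.chains, config.lv)
        results[state] = StateResult(
            state=state, dataset=clean, report=report, split=split, grid=grid
        )
    if config.output_dir is not None:
        write_artifacts(results, config, Path(config.output_dir))
    return results


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def metrics_table(results: dict[str, StateResult]) -> list[dict]:
    return [row.as_row() for res in results.values() for row in res.grid.rows]


def write_artifacts(
    results: dict[str, StateResult], config: PipelineConfig, outdir: Path
) -> None:
    """Write metrics.csv, outliers.json, split.json, predictions.csv and
    report.json with deterministic formatting."""
    outdir.mkdir(parents=True, exist_ok=True)
    rows = metrics_table(results)
    with open(outdir / "metrics.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        for row in rows:
            writer.writerow(
                {
                    k: (f"{v:.6f}" if isinstance(v, float) and math.isfinite(v) else v)
                    for k, v in row.items()
                }
            )
    outliers = {}
    splits = {}
    predictions: list[dict] = []
    best_summary = {}
    for state, res in results.items():
        outliers[state] = {
            "spectral_outlier_ids": res.report.spectral_outlier_ids,
            "chemical_outlier_ids": res.report.chemical_outlier_ids,
            "removed_ids": res.report.removed_ids,
            "md_threshold": res.report.md_threshold,
            "residual_sd": res.report.residual_sd,
            "k_components": res.report.k_components,
            "residual_n_lv": res.report.residual_n_lv,
        }
        splits[state] = {
            "calibration_ids": res.split.calibration_ids,
            "prediction_ids": res.split.prediction_ids,
            "calibration_fraction": res.split.calibration_fraction,
        }
        if res.grid.best is not None:
            best_summary[state] = res.grid.best.as_row()
            # refit the winning cell to emit measured-vs-predicted pairs
            chain = parse_chain(res.grid.best.chain)
            cal = res.dataset.subset(res.split.calibration_ids)
            pred = res.dataset.subset(res.split.prediction_ids)
            X_cal, X_pred = chain.fit_transform(
                cal.absorbance, pred.absorbance, res.dataset.wavelengths
            )
            model = plsr_fit(
                X_cal, cal.reference, res.grid.best.n_lv, on_rank_deficient="truncate"
            )
            yhat = plsr_predict(model, X_pred)
            for sid, measured, predicted in zip(pred.sample_ids, pred.reference, yhat):
                predictions.append(
                    {
                        "state": state,
                        "chain": res.grid.best.chain,
                        "sample_id": int(sid),
                        "measured": f"{measured:.4f}",
                        "predicted": f"{predicted:.4f}",
                    }
                )
    (outdir / "outliers.json").write_text(json.dumps(outliers, indent=2))
    (outdir / "split.json").write_text(json.dumps(splits, indent=2))
    with open(outdir / "predictions.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["state", "chain", "sample_id", "measured", "predicted"]
        )
        writer.writeheader()
        writer.writerows(predictions)
    report = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "states": list(config.states),
        "chains": list(config.chains),
        "split_fraction": config.split_fraction,
        "best_models": best_summary,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
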