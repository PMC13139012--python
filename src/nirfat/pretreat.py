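"""Spectral pretreatment operators and their ordered composition.

All operators act row-wise (one spectrum per row) and preserve matrix
shape.  The only fitted state in the vocabulary is MSC's reference
spectrum, which must be estimated on the calibration set and applied
unchanged to prediction spectra.

Chain names follow the conventional labels used in chemometrics model
grids: ``Original, 1-Der, 2-Der, SG, Normalize, Baseline, SNV, MSC,
1-Der + SNV, 2-Der + SNV, SG + SNV`` — read left to right ("SG + SNV"
means Savitzky-Golay smoothing, then SNV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import savgol_filter


class PretreatError(ValueError):
    pass


# sample SD (ddof=1) is the convention throughout the package
_DDOF = 1


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-row centering and scaling to unit SD.

    Uses the sample SD (ddof=1).  A constant row has no scale and raises
    ``PretreatError`` naming the offending row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=_DDOF, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise PretreatError(f"constant spectrum in row(s) {bad.tolist()}: SNV undefined")
    return (X - mean) / sd


def msc_fit(X_calibration: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the column mean of the calibration matrix."""
    X = np.atleast_2d(np.asarray(X_calibration, dtype=float))
    if X.shape[0] < 2:
        raise PretreatError("MSC reference needs at least 2 calibration spectra")
    return X.mean(axis=0)


def msc_apply(X: np.ndarray, reference: np.ndarray, slope_tol: float = 1e-8) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x ~ a + b * reference (ordinary least
    squares); the corrected row is (x - a) / b.  Rows whose fitted slope
    magnitude falls below ``slope_tol`` cannot be corrected and raise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if reference.size != X.shape[1]:
        raise PretreatError(
            f"reference length {reference.size} != {X.shape[1]} wavelengths"
        )
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise PretreatError("constant MSC reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = X.mean(axis=1) - b * reference.mean()
    bad = np.flatnonzero(np.abs(b) < slope_tol)
    if bad.size:
        raise PretreatError(f"uncorrectable spectrum in row(s) {bad.tolist()}: |slope| < {slope_tol}")
    return (X - a[:, None]) / b[:, None]


def savitzky_golay(
    X: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 0,
    wavelength_step: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative filter, same-length output.

    Local least-squares polynomial convolution; edges are handled by
    evaluating the edge-window polynomial fits at the edge positions so
    wavelength alignment is preserved.  Derivatives are scaled by
    ``wavelength_step**-deriv`` (per-nm units).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window <= polyorder:
        raise PretreatError(f"window must be odd and > polyorder, got {window}, {polyorder}")
    if window > X.shape[1]:
        raise PretreatError(f"window {window} exceeds {X.shape[1]} wavelengths")
    if deriv > polyorder:
        raise PretreatError("derivative order cannot exceed polynomial order")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=wavelength_step, axis=1, mode="interp",
    )


def normalize_vector(X: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if bad.size:
        raise PretreatError(f"zero spectrum in row(s) {bad.tolist()}: cannot normalize")
    return X / norms


def normalize_minmax(X: np.ndarray) -> np.ndarray:
    """Alternative normalization: per-row min-max scaling to [0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lo = X.min(axis=1, keepdims=True)
    span = X.max(axis=1, keepdims=True) - lo
    bad = np.flatnonzero(span.ravel() == 0)
    if bad.size:
        raise PretreatError(f"constant spectrum in row(s) {bad.tolist()}")
    return (X - lo) / span


def normalize_area(X: np.ndarray) -> np.ndarray:
    """Alternative normalization: per-row division by total absolute area."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    area = np.abs(X).sum(axis=1, keepdims=True)
    bad = np.flatnonzero(area.ravel() == 0)
    if bad.size:
        raise PretreatError(f"zero spectrum in row(s) {bad.tolist()}")
    return X / area


def baseline_detrend(X: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Subtract each row's least-squares straight line over wavelength.

    Removes the additive offset-plus-drift component attributed to
    scattering; output rows are orthogonal to span{1, lambda}.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size != X.shape[1]:
        raise PretreatError(f"wavelengths length {wl.size} != {X.shape[1]} columns")
    if wl.size < 2:
        raise PretreatError("need at least 2 wavelengths to detrend")
    design = np.column_stack([np.ones_like(wl), wl])
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return X - (design @ coef).T


# ---------------------------------------------------------------------------
# steps and chains
# ---------------------------------------------------------------------------

@dataclass
class PreprocessStep:
    """One pretreatment operator with parameters and optional fitted state.

    ``kind`` is one of ``sg, deriv1, deriv2, snv, msc, normalize,
    baseline``.  Only ``msc`` requires fitting (its reference spectrum);
    ``fitted_state`` holds that reference after :meth:`fit`.
    """

    kind: str
    params: dict = field(default_factory=dict)
    fitted_state: np.ndarray | None = None

    _KINDS = ("sg", "deriv1", "deriv2", "snv", "msc", "normalize", "baseline")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise PretreatError(f"unknown pretreatment kind {self.kind!r}")

    @property
    def requires_fit(self) -> bool:
        return self.kind == "msc"

    def fit(self, X: np.ndarray) -> "PreprocessStep":
        if self.kind == "msc":
            self.fitted_state = msc_fit(X)
        return self

    def apply(self, X: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        step = float(np.median(np.diff(wavelengths))) if len(wavelengths) > 1 else 1.0
        if self.kind == "snv":
            return snv(X)
        if self.kind == "normalize":
            method = self.params.get("method", "vector")
            fn = {"vector": normalize_vector, "minmax": normalize_minmax, "area": normalize_area}
            if method not in fn:
                raise PretreatError(f"unknown normalize method {method!r}")
            return fn[method](X)
        if self.kind == "baseline":
            return baseline_detrend(X, wavelengths)
        if self.kind == "msc":
            if self.fitted_state is None:
                raise PretreatError("MSC step applied before fit")
            return msc_apply(X, self.fitted_state)
        if self.kind == "sg":
            return savitzky_golay(
                X,
                window=self.params.get("window", 11),
                polyorder=self.params.get("polyorder", 2),
                deriv=0,
                wavelength_step=step,
            )
        if self.kind == "deriv1":
            return savitzky_golay(
                X,
                window=self.params.get("window", 11),
                polyorder=self.params.get("polyorder", 2),
                deriv=1,
                wavelength_step=step,
            )
        if self.kind == "deriv2":
            return savitzky_golay(
                X,
                window=self.params.get("window", 11),
                polyorder=self.params.get("polyorder", 3),
                deriv=2,
                wavelength_step=step,
            )
        raise PretreatError(f"unknown pretreatment kind {self.kind!r}")


@dataclass
class PreprocessChain:
    """An ordered list of pretreatment steps with a display name."""

    steps: list[PreprocessStep] = field(default_factory=list)
    name: str = "Original"

    def fit(self, X_fit: np.ndarray, wavelengths: np.ndarray) -> "PreprocessChain":
        """Fit the chain's stateful steps on calibration spectra only.

        Each step is fitted on the output of the preceding steps, exactly
        as it will later see transformed data.
        """
        current = np.atleast_2d(np.asarray(X_fit, dtype=float))
        for step in self.steps:
            if step.requires_fit:
                step.fit(current)
            current = step.apply(current, wavelengths)
        return self

    def transform(self, X: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        current = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            current = step.apply(current, wavelengths)
        return current

    def fit_transform(
        self, X_fit: np.ndarray, X_transform: np.ndarray, wavelengths: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        self.fit(X_fit, wavelengths)
        return self.transform(X_fit, wavelengths), self.transform(X_transform, wavelengths)


def apply_chain(
    chain: PreprocessChain,
    X_fit: np.ndarray,
    X_transform: np.ndarray,
    wavelengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a chain on ``X_fit`` and transform both matrices.

    Fit-requiring steps (MSC) estimate their state from ``X_fit`` only,
    then apply it to both, preventing calibration/prediction leakage.
    """
    return chain.fit_transform(X_fit, X_transform, wavelengths)


#: chain vocabulary used in model-grid tables
CHAIN_NAMES = (
    "Original", "1-Der", "2-Der", "SG", "Normalize", "Baseline",
    "SNV", "MSC", "1-Der + SNV", "2-Der + SNV", "SG + SNV",
)

_SINGLE: dict[str, Callable[[], PreprocessStep]] = {
    "Original": None,  # sentinel: empty chain
    "1-Der": lambda: PreprocessStep("deriv1"),
    "2-Der": lambda: PreprocessStep("deriv2"),
    "SG": lambda: PreprocessStep("sg"),
    "Normalize": lambda: PreprocessStep("normalize"),
    "Baseline": lambda: PreprocessStep("baseline"),
    "SNV": lambda: PreprocessStep("snv"),
    "MSC": lambda: PreprocessStep("msc"),
}


def parse_chain(name: str) -> PreprocessChain:
    """Build a fresh chain from a display name like ``"SG + SNV"``.

    Components are separated by ``+`` and applied left to right.
    """
    label = name.strip()
    if label == "Original":
        return PreprocessChain(steps=[], name="Original")
    steps: list[PreprocessStep] = []
    for part in label.split("+"):
        part = part.strip()
        if part not in _SINGLE or _SINGLE[part] is None:
            raise PretreatError(f"unknown pretreatment name {part!r} in chain {name!r}")
        steps.append(_SINGLE[part]())
    return PreprocessChain(steps=steps, name=label)
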