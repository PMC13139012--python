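"""Synthetic portable-NIR kernel datasets.

No public spectral archive exists for hard-shelled nut kernels measured in
the three presentations this pipeline targets (in-shell kernels, de-shelled
kernels, kernel granules), so this module generates datasets with the
statistical structure the downstream chemometrics assumes:

* reference fat values drawn from a truncated normal whose moments and
  range match gravimetric (Soxhlet) fat assays of *Torreya grandis*
  kernels (40.85-75.43 %, mean 54.63 %, SD 11.2);
* absorbance spectra on a 1,000-1,650 nm grid at 1 nm with Gaussian
  absorption bands near 1,200 nm (ester C-O-C, fat-coupled) and 1,450 nm
  (O-H/N-H, largely fat-independent) over a smooth low-order background;
* per-state physical effects — multiplicative scatter, additive baseline
  offset and drift, signal attenuation, smooth sample heterogeneity and
  detector noise — whose default magnitudes reproduce the qualitative
  ordering seen on real instruments: mean absorbance
  granules > de-shelled > in-shell, and scan-to-scan variability
  in-shell > de-shelled > granules;
* triplicate scans averaged to one spectrum per sample, and optional
  planted spectral/chemical outliers with recorded ground truth.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .specio import STATES, SpectralDataset


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Soxhlet reference chemistry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoxhletMeasurement:
    """One gravimetric fat determination.

    Attributes
    ----------
    m0 : float
        Mass of the empty receiving flask (g).
    m1 : float
        Mass of the flask plus extracted fat after drying to constant
        mass (g).
    m : float
        Mass of the kernel-granule sample loaded into the thimble (g).
    """

    m0: float
    m1: float
    m: float


def soxhlet_fat(meas: SoxhletMeasurement) -> float:
    """Fat content F = (m1 - m0) / m x 100, in % (w/w).

    Raises ``GeneratorConfigError`` for a non-positive sample mass or a
    final flask mass below the tare (negative extract).
    """
    if meas.m <= 0:
        raise GeneratorConfigError(f"sample mass must be positive, got {meas.m}")
    if meas.m1 < meas.m0:
        raise GeneratorConfigError(
            f"flask+fat mass {meas.m1} below empty-flask mass {meas.m0}"
        )
    return (meas.m1 - meas.m0) / meas.m * 100.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``amplitude(fat) = fat_amp * fat/100 + base_amp`` at the band center;
    the profile is ``exp(-(lambda-center)^2 / (2 width^2))``.
    """

    center: float  # nm
    width: float   # nm (Gaussian sigma)
    fat_amp: float  # AU per unit fat fraction (fat-coupled)
    base_amp: float  # AU, fat-independent


@dataclass(frozen=True)
class StateParams:
    """Physical-state effect magnitudes applied to each replicate scan.

    scatter_sd
        SD of the multiplicative scatter factor ``a ~ N(1, scatter_sd)``.
    offset_sd
        SD of the additive baseline offset ``b`` (AU).
    slope_sd
        SD of the linear baseline drift (AU per nm, applied about the
        grid midpoint).
    attenuation
        Deterministic signal attenuation in (0, 1]; models loss of
        effective light-sample interaction (1 = none).
    noise_sd
        SD of iid detector noise per wavelength (AU).
    level_shift
        Deterministic mean absorbance offset (AU); encodes how strongly
        the presentation absorbs overall.
    heterogeneity_sd
        Amplitude SD of smooth random spectral deviations per scan
        position (AU); models surface/particle heterogeneity that no
        row-wise pretreatment can fully remove.
    """

    scatter_sd: float
    offset_sd: float
    slope_sd: float
    attenuation: float
    noise_sd: float
    level_shift: float
    heterogeneity_sd: float


def _default_bands() -> tuple[Band, ...]:
    return (
        Band(center=1200.0, width=40.0, fat_amp=0.55, base_amp=0.05),
        Band(center=1450.0, width=55.0, fat_amp=0.06, base_amp=0.38),
    )


def _default_state_params() -> dict[str, StateParams]:
    # Magnitudes ordered in-shell > de-shelled > granules for scatter,
    # drift, noise and heterogeneity; mean level and attenuation ordered
    # granules > de-shelled > in-shell.
    return {
        "in_shell": StateParams(
            scatter_sd=0.20, offset_sd=0.080, slope_sd=2.5e-4,
            attenuation=0.60, noise_sd=0.006, level_shift=0.0,
            heterogeneity_sd=0.030,
        ),
        "de_shelled": StateParams(
            scatter_sd=0.16, offset_sd=0.050, slope_sd=1.2e-4,
            attenuation=0.85, noise_sd=0.004, level_shift=0.12,
            heterogeneity_sd=0.028,
        ),
        "granules": StateParams(
            scatter_sd=0.13, offset_sd=0.040, slope_sd=0.5e-4,
            attenuation=1.0, noise_sd=0.003, level_shift=0.25,
            heterogeneity_sd=0.026,
        ),
    }


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic acquisition campaign."""

    n_samples: int = 210
    wavelength_start: float = 1000.0
    wavelength_stop: float = 1650.0
    wavelength_step: float = 1.0
    fat_mean: float = 54.63
    fat_sd: float = 11.2
    fat_min: float = 40.85
    fat_max: float = 75.43
    band_params: tuple[Band, ...] = field(default_factory=_default_bands)
    state_params: dict[str, StateParams] = field(default_factory=_default_state_params)
    n_spectral_outliers: int = 0
    n_chemical_outliers: int = 0
    spectral_outlier_magnitude: float = 0.7   # AU bump amplitude
    chemical_outlier_magnitude: float = 25.0  # % fat shift (gross assay fault)
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise GeneratorConfigError("n_samples must be >= 1")
        if self.wavelength_step <= 0 or self.wavelength_stop <= self.wavelength_start:
            raise GeneratorConfigError("wavelength grid must be strictly increasing")
        if not (self.fat_min < self.fat_mean < self.fat_max):
            raise GeneratorConfigError("require fat_min < fat_mean < fat_max")
        if self.fat_sd < 0:
            raise GeneratorConfigError("fat_sd must be >= 0")
        if self.replicate_count < 1:
            raise GeneratorConfigError("replicate_count must be >= 1")
        if self.n_spectral_outliers < 0 or self.n_chemical_outliers < 0:
            raise GeneratorConfigError("outlier counts must be >= 0")
        if self.n_spectral_outliers + self.n_chemical_outliers > self.n_samples:
            raise GeneratorConfigError("more planted outliers than samples")
        if self.n_spectral_outliers > 0 and self.spectral_outlier_magnitude <= 0:
            raise GeneratorConfigError("spectral_outlier_magnitude must be > 0")
        if self.n_chemical_outliers > 0 and self.chemical_outlier_magnitude <= 0:
            raise GeneratorConfigError("chemical_outlier_magnitude must be > 0")
        for state, sp in self.state_params.items():
            if not 0 < sp.attenuation <= 1:
                raise GeneratorConfigError(f"{state}: attenuation must be in (0, 1]")
            for name in ("scatter_sd", "offset_sd", "slope_sd", "noise_sd", "heterogeneity_sd"):
                if getattr(sp, name) < 0:
                    raise GeneratorConfigError(f"{state}: {name} must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start,
            self.wavelength_stop + 0.5 * self.wavelength_step,
            self.wavelength_step,
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded while planting outliers."""

    true_spectral_outlier_ids: set[int] = field(default_factory=set)
    true_chemical_outlier_ids: set[int] = field(default_factory=set)
    clean_reference_values: np.ndarray | None = None

    def validate(self, sample_ids: np.ndarray) -> None:
        ids = set(int(s) for s in sample_ids)
        if self.true_spectral_outlier_ids & self.true_chemical_outlier_ids:
            raise GeneratorConfigError("outlier id sets must be disjoint")
        if not (self.true_spectral_outlier_ids | self.true_chemical_outlier_ids) <= ids:
            raise GeneratorConfigError("outlier ids must be a subset of dataset ids")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _loc_for_truncated_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Center of the underlying normal whose [lo, hi]-truncation has the
    requested mean.

    Truncating an asymmetric interval shifts the mean (centering the
    normal at the target would overshoot it by >1 % fat here), so the
    location is solved for instead.  The truncated mean is strictly
    increasing in the location, so bisection is safe.
    """
    from scipy.optimize import brentq

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(brentq(lambda L: truncated_mean(L) - target, lo - 10 * sd, hi + 10 * sd, xtol=1e-10))


def sample_fat_values(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw n reference fat values (%) from a truncated normal.

    The underlying normal has SD ``fat_sd`` and its location is chosen so
    the truncated distribution's mean equals ``fat_mean`` — the generated
    sample then reproduces the assayed mean, not a truncation-shifted
    one.  A degenerate ``fat_sd = 0`` returns the mean for every sample.
    """
    if n < 1:
        raise GeneratorConfigError("n must be >= 1")
    if cfg.fat_min >= cfg.fat_max:
        raise GeneratorConfigError("fat_min must be < fat_max")
    if cfg.fat_sd == 0:
        return np.full(n, cfg.fat_mean)
    loc = _loc_for_truncated_mean(cfg.fat_mean, cfg.fat_sd, cfg.fat_min, cfg.fat_max)
    a = (cfg.fat_min - loc) / cfg.fat_sd
    b = (cfg.fat_max - loc) / cfg.fat_sd
    return stats.truncnorm.rvs(
        a, b, loc=loc, scale=cfg.fat_sd, size=n, random_state=rng
    )


def synthesize_clean_spectrum(fat: float, cfg: GeneratorConfig) -> np.ndarray:
    """Noise-free absorbance for one sample at the given fat content (%).

    The spectrum is a sum of Gaussian bands whose amplitudes are affine in
    fat, over a smooth quadratic background — strictly deterministic and,
    at every wavelength, linear in fat.
    """
    if len(cfg.band_params) == 0:
        raise GeneratorConfigError("band_params must contain at least one band")
    wl = cfg.wavelengths
    u = (wl - cfg.wavelength_start) / (cfg.wavelength_stop - cfg.wavelength_start)
    background = 0.25 + 0.06 * u + 0.02 * u**2
    spectrum = background.copy()
    for band in cfg.band_params:
        amp = band.fat_amp * fat / 100.0 + band.base_amp
        spectrum += amp * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
    return spectrum


def _heterogeneity_curve(
    wl: np.ndarray, sd: float, rng: np.random.Generator, n_bumps: int = 6
) -> np.ndarray:
    """Smooth random deviation: a few broad Gaussian bumps per scan."""
    if sd == 0:
        # keep the rng stream position identical regardless of sd
        rng.normal(size=n_bumps)
        rng.uniform(size=2 * n_bumps)
        return np.zeros_like(wl)
    centers = rng.uniform(wl[0], wl[-1], size=n_bumps)
    widths = rng.uniform(30.0, 80.0, size=n_bumps)
    amps = rng.normal(0.0, sd, size=n_bumps)
    curve = np.zeros_like(wl)
    for c, w, a in zip(centers, widths, amps):
        curve += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return curve


def apply_state_effects(
    spectrum: np.ndarray,
    state: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one replicate's worth of physical-state distortions.

    Returns ``a * (attenuation * spectrum) + b + slope * (lambda - mid)
    + level_shift + heterogeneity + noise`` with ``a``, ``b``, ``slope``
    and the heterogeneity curve drawn fresh per call (per replicate scan).
    """
    if state not in cfg.state_params:
        raise GeneratorConfigError(f"no state_params entry for state {state!r}")
    sp = cfg.state_params[state]
    wl = cfg.wavelengths
    a = rng.normal(1.0, sp.scatter_sd)
    b = rng.normal(0.0, sp.offset_sd)
    slope = rng.normal(0.0, sp.slope_sd)
    hetero = _heterogeneity_curve(wl, sp.heterogeneity_sd, rng)
    noise = rng.normal(0.0, sp.noise_sd, size=wl.size) if sp.noise_sd > 0 else 0.0
    mid = 0.5 * (wl[0] + wl[-1])
    return (
        a * (sp.attenuation * np.asarray(spectrum, dtype=float))
        + b
        + slope * (wl - mid)
        + sp.level_shift
        + hetero
        + noise
    )


def _spectral_distortion(
    wl: np.ndarray, magnitude: float, rng: np.random.Generator
) -> np.ndarray:
    """A localized absorbance artifact emulating an acquisition fault."""
    center = rng.uniform(wl[0] + 50, wl[-1] - 50)
    width = rng.uniform(10.0, 30.0)
    sign = rng.choice([-1.0, 1.0])
    return sign * magnitude * np.exp(-0.5 * ((wl - center) / width) ** 2)


def inject_outliers(
    dataset: SpectralDataset,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[SpectralDataset, SyntheticTruth]:
    """Plant spectral and chemical outliers; record ground truth.

    Spectral outliers receive a large localized spectral artifact;
    chemical outliers have their recorded reference fat value shifted
    (the spectrum stays truthful) — mimicking an error in the wet
    chemistry or data entry.  The two planted sets are disjoint and all
    other rows are untouched.
    """
    n_spec, n_chem = cfg.n_spectral_outliers, cfg.n_chemical_outliers
    truth = SyntheticTruth(
        clean_reference_values=None
        if dataset.reference is None
        else dataset.reference.copy()
    )
    if n_spec + n_chem == 0:
        return dataset, truth
    if n_spec + n_chem > dataset.n_samples:
        raise GeneratorConfigError("more planted outliers than samples")
    if n_chem > 0 and dataset.reference is None:
        raise GeneratorConfigError("chemical outliers need reference values")
    picks = rng.choice(dataset.sample_ids, size=n_spec + n_chem, replace=False)
    spec_ids = set(int(s) for s in picks[:n_spec])
    chem_ids = set(int(s) for s in picks[n_spec:])
    absorbance = dataset.absorbance.copy()
    reference = None if dataset.reference is None else dataset.reference.copy()
    for row, sid in enumerate(dataset.sample_ids):
        sid = int(sid)
        if sid in spec_ids:
            absorbance[row] += _spectral_distortion(
                dataset.wavelengths, cfg.spectral_outlier_magnitude, rng
            )
        elif sid in chem_ids:
            shift = rng.choice([-1.0, 1.0]) * cfg.chemical_outlier_magnitude
            reference[row] += shift
    corrupted = replace(dataset, absorbance=absorbance, reference=reference)
    truth.true_spectral_outlier_ids = spec_ids
    truth.true_chemical_outlier_ids = chem_ids
    truth.validate(dataset.sample_ids)
    return corrupted, truth


def generate_dataset(
    cfg: GeneratorConfig, state: str, rng: np.random.Generator | None = None
) -> tuple[SpectralDataset, SyntheticTruth]:
    """Generate one full averaged-replicate dataset for a physical state.

    Per sample, ``replicate_count`` state-affected scans are generated and
    averaged into a single spectrum, as a triplicate-scan acquisition
    protocol would.  Sample ids run 1..n.  Reproducible bit-for-bit given
    the same config and seed.
    """
    cfg.validate()
    if state not in cfg.state_params:
        raise GeneratorConfigError(f"no state_params entry for state {state!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fats = sample_fat_values(cfg.n_samples, cfg, rng)
    wl = cfg.wavelengths
    absorbance = np.empty((cfg.n_samples, wl.size))
    for i, fat in enumerate(fats):
        clean = synthesize_clean_spectrum(fat, cfg)
        reps = [
            apply_state_effects(clean, state, cfg, rng)
            for _ in range(cfg.replicate_count)
        ]
        absorbance[i] = np.mean(reps, axis=0)
    dataset = SpectralDataset(
        wavelengths=wl,
        absorbance=absorbance,
        sample_ids=np.arange(1, cfg.n_samples + 1),
        reference=fats,
        state=state,
    )
    return inject_outliers(dataset, cfg, rng)
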