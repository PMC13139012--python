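# Methods

This note documents the models, numerical conventions and design choices
behind `nirfat`, and what the synthetic-data generator does and does not
emulate.

## The calibration problem

Fat content in tree-nut kernels absorbs in the short-wave NIR through
C–H/ester overtones (a band near 1,200 nm) while water/protein-related
O–H/N–H absorption dominates near 1,450 nm. A portable spectrometer
measuring 1,000–1,650 nm at 1 nm therefore carries enough information to
regress fat content on absorbance, provided physical nuisance variation
(scatter, baseline drift, shell attenuation) is handled. The pipeline
quantifies how much the sample's physical presentation — in-shell,
de-shelled, or ground to granules — limits the achievable accuracy.

## Synthetic data generator (`simkernel`)

**Reference values.** Fat references are drawn from a normal distribution
truncated to the assayed range [40.85, 75.43] %. The location of the
underlying normal (SD fixed at 11.2) is solved by bisection so that the
*truncated* mean equals the assayed mean 54.63 % — naive truncation of an
asymmetric interval would shift the sample mean up by ≈1.5 points. Two
emulation limits follow and are accepted: (i) no truncated normal on this
range can reach a sample SD of 11.2 (the σ→∞ uniform limit gives ≈10.0);
generated samples have SD ≈ 8.3; (ii) the generated range is a subset of
the configured range rather than attaining it exactly at n = 210.

**Spectra.** A clean spectrum is a smooth quadratic background plus
Gaussian bands; each band amplitude is affine in fat
(`fat_amp·fat/100 + base_amp`). Defaults: a fat-coupled band at 1,200 nm
(σ = 40 nm) and a mostly fat-independent matrix band at 1,450 nm
(σ = 55 nm). Whether the 1,450 nm feature is partly fat-coupled is
spectroscopically ambiguous (O–H vs. N–H assignments in the nut
literature); the generator treats it as predominantly matrix absorption
and exposes both amplitudes in configuration.

**State effects.** Each replicate scan applies, per spectrum:

| parameter | in-shell | de-shelled | granules | meaning |
|---|---|---|---|---|
| `scatter_sd` | 0.20 | 0.16 | 0.13 | multiplicative scatter `a ~ N(1, ·)` |
| `offset_sd` (AU) | 0.080 | 0.050 | 0.040 | additive baseline offset |
| `slope_sd` (AU/nm) | 2.5e-4 | 1.2e-4 | 0.5e-4 | linear baseline drift |
| `attenuation` | 0.60 | 0.85 | 1.00 | deterministic signal loss |
| `noise_sd` (AU) | 0.006 | 0.004 | 0.003 | iid detector noise |
| `level_shift` (AU) | 0.00 | 0.12 | 0.25 | mean absorbance offset |
| `heterogeneity_sd` (AU) | 0.030 | 0.028 | 0.026 | smooth per-scan deviations |

The heterogeneity term — a random sum of six broad Gaussian bumps per
scan — deserves comment. Multiplicative scatter, offsets and drift are
(almost) exactly removable by SNV/MSC/detrending, and iid noise averages
out over 651 channels, so a generator with only those effects produces
models that are either near-perfect or uniformly poor. Real spectra are
limited instead by smooth, sample-specific deviations (surface
irregularity, particle-size variation, packing) that row-wise
pretreatment cannot remove because they are not affine in the reference
spectrum. The heterogeneity term supplies exactly that nuisance; its
magnitude is the main knob that sets each state's achievable prediction
accuracy. Default magnitudes were chosen once so that, over seed panels,
mean best-model R²p is ≈0.90 (granules), ≈0.83 (de-shelled) and ≈0.65
(in-shell) — the accuracy bands and ordering reported for this class of
instrument and sample — and so that scatter-correcting pretreatment
visibly beats raw spectra on granule data.

**Averaging and outliers.** Three replicate scans are averaged per sample
(variance of each stochastic component scales as 1/k, tested). Planted
spectral outliers add a localized absorbance artifact (default 0.7 AU,
10–30 nm wide, random sign/position) — a shape anomaly that survives any
normalization. Planted chemical outliers shift the *recorded* reference
value by ±25 % fat while the spectrum stays truthful, emulating a gross
assay or transcription fault; the magnitude is set at roughly ten times
the screening model's clean residual SD for the hardest state, the scale
at which a 2.5·SD rule can reliably find it. Ground truth (ids, clean
references) is returned alongside every generated dataset.

**What the generator does not emulate:** radiative transfer or
Kubelka–Munk physics, instrument line-shape, wavelength miscalibration,
moisture/temperature drift, and nonlinear fat–absorbance response.
Passing tests therefore demonstrate the *chemometric machinery* under
realistic statistical structure, not instrument-grade realism.

## Pretreatment (`pretreat`)

All operators are row-wise and shape-preserving; sample SD (ddof = 1) is
used everywhere a SD appears (SNV, residual screening, RPD).

* **SNV** — per-row (x − mean)/SD; idempotent; constant rows are errors.
* **MSC** — reference = calibration column mean; per-row OLS `x ≈ a + b·ref`,
  corrected row = (x − a)/b; |b| < 1e-8 is an error. The reference is
  fitted on calibration rows only and reused for prediction rows.
* **Savitzky–Golay** — scipy's filter with `mode="interp"` (edge windows
  evaluated at edge positions, so output length and wavelength alignment
  are preserved) and `delta = grid step` (derivatives in per-nm units).
  Defaults: window 11, polyorder 2 (smoothing, 1st derivative),
  polyorder 3 (2nd derivative). The plain `1-Der`/`2-Der` grid entries
  are SG derivative filters with these defaults.
* **Normalize** — per-row unit Euclidean norm (the most common reading of
  "normalize" in chemometrics software); min–max and area variants are
  available but non-default, since the convention is genuinely ambiguous.
* **Baseline** — per-row linear detrend over wavelength (offset + drift
  removal); higher-order detrending is out of scope.

Chains compose left to right (`"SG + SNV"` = SG, then SNV) and the
vocabulary matches the model-grid row labels.

## Factor models (`factormodels`)

**PCA** is the SVD of the mean-centered matrix; explained ratios are
score variances over total centered variance; loadings carry a
deterministic sign convention (largest-magnitude element positive).
Screening PCA is fitted on the full pre-split dataset, consistent with
removing outliers before partitioning.

**PLSR** uses NIPALS (PLS1): per component the weight is the closed-form
`w ∝ X'y`, scores `t = Xw`, loadings `p = X't/t't`, `q = y't/t't`, with
deflation of both blocks; the regression vector is `B = W(P'W)⁻¹q`. X is
centered but not autoscaled — scale handling belongs to the pretreatment
chain. NIPALS was chosen over SIMPLS because each component can be
verified directly against its defining recursion (and externally against
scikit-learn in the test suite). Rank deficiency either raises or
truncates, per flag.

**Latent-variable selection** is 5-fold venetian-blind cross-validation
over counts 1–15, argmin RMSECV with ties to the smaller count. One
NIPALS fit at the maximum count per fold provides all truncations, so the
grid costs one fit, not fifteen.

## Outlier screening (`screen`)

Stage 1 (spectral): the state's screening chain (Normalize for intact
kernels, MSC for granules) is applied, PCA fitted, k = 4 components kept
(their cumulative explained variance exceeds 0.99 on this data class; a
cumulative-threshold rule is available instead of the fixed k), and
`MD² > χ²(k)` at 95 % confidence flags a sample. The chi-square cutoff is
the large-n reading of a score-space confidence ellipse; a Hotelling-T²/F
cutoff is available behind a flag for small n. Under a Gaussian null this
flags ≈5 % of samples by construction — on a 200-sample dataset a handful
of false flags is expected behaviour, not a bug.

Stage 2 (chemical), on the spectral survivors: a PLSR of y on the
pretreated spectra (LV count by CV) provides **out-of-fold** residuals;
`|residual| > 2.5·SD(residuals)` flags a sample, in a single pass. Two
deliberate choices here: (i) cross-validated rather than training
residuals, because a flexible latent-variable model fitted on all rows
can absorb a shifted reference value and zero out exactly the residual
the screen needs (measured: training-residual screening missed most
planted faults in the noisiest state); (ii) the same pretreatment as the
spectral stage rather than raw spectra, because the screen's power is
bounded by the model's residual SD and raw in-shell spectra roughly
double it. Both stages run once; there is no iterative re-screening.

## SPXY partitioning (`spxy`)

Joint distance `D = Dx/max(Dx) + Dy/max(Dy)` (Euclidean on raw averaged
spectra; |Δy| on references), greedy max–min selection seeded with the
globally most distant pair, calibration size `⌊0.75·n⌋` (the floor is the
unique convention consistent with 202→151, 203→152, 205→153). All ties
break toward the smallest sample id, which makes the split deterministic
and invariant under row permutation. Distances are computed on raw
spectra: the split must be common to all pretreatment chains in the
grid, so it cannot depend on any one of them.

## Metrics and model selection (`calibrate`)

R² is 1 − SSE/SST (not squared correlation); RMSE uses divisor n;
RPD = SD(y_pred, ddof=1)/RMSEP; RER = range(y_pred)/RMSEP. RPD and RER
report infinity when RMSEP is at numerical-noise scale (degenerate
perfect fits on noiseless fixtures). The best cell maximizes R²p with
RMSEP as tie-break. Failed grid cells (e.g. a pretreatment that rejects
degenerate input) are recorded as error rows so the grid always renders
completely. Leakage control is structural: the pretreatment fit, the LV
choice and the regression coefficients see calibration rows only, and a
test perturbs prediction rows to assert the fitted model is bit-identical.

## Problem sizes in the standard runs

Unit tests run on reduced problems (40–80 samples, 5 nm grid) where the
property under test does not depend on size; acceptance-level checks use
the full 210 × 651 acquisition. Panel statistics (state ordering,
screening recovery) use 20 seeds in the test suite and 10 seeds in
`scripts/acceptance.py`; at these sizes the panel means are stable to
well within the margins asserted.

## Known limitations

* The generator's parameter defaults are a calibration to plausible
  accuracy bands, not physical constants; absolute R²/RMSE values from
  synthetic data should not be read as instrument performance claims.
* The reference-value distribution cannot simultaneously match the
  assayed mean, SD and range (see above); mean and range are honored.
* PLSR is linear; strongly nonlinear fat–absorbance relationships (not
  emulated) would require kernel or local variants that are out of scope.
* Screening is single-pass by design; masked outliers that only emerge
  after a first removal round are not pursued.
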