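"""Generator: reference chemistry, band model, state effects, outliers."""

import numpy as np
import pytest
from scipy import integrate

from nirfat.simkernel import (
    Band,
    GeneratorConfig,
    GeneratorConfigError,
    SoxhletMeasurement,
    StateParams,
    apply_state_effects,
    generate_dataset,
    inject_outliers,
    sample_fat_values,
    soxhlet_fat,
    synthesize_clean_spectrum,
)

STATES = ("in_shell", "de_shelled", "granules")


class TestSoxhlet:
    @pytest.mark.parametrize(
        "m0,m1,m,expected",
        [
            (100.0, 101.1, 2.0, 55.0),
            (100.0, 100.0, 2.0, 0.0),
            (50.0, 51.5086, 2.0, 75.43),
        ],
    )
    def test_gravimetric_formula(self, m0, m1, m, expected):
        assert soxhlet_fat(SoxhletMeasurement(m0=m0, m1=m1, m=m)) == pytest.approx(expected)

    def test_invalid_masses_raise(self):
        with pytest.raises(GeneratorConfigError):
            soxhlet_fat(SoxhletMeasurement(m0=100.0, m1=101.0, m=0.0))
        with pytest.raises(GeneratorConfigError):
            soxhlet_fat(SoxhletMeasurement(m0=100.0, m1=99.0, m=2.0))


class TestFatDistribution:
    def test_degenerate_sd_returns_mean(self, rng):
        cfg = GeneratorConfig(fat_sd=0.0)
        values = sample_fat_values(5, cfg, rng)
        assert np.all(values == cfg.fat_mean)

    def test_truncation_bounds(self, default_config, rng):
        values = sample_fat_values(210, default_config, rng)
        assert values.min() >= default_config.fat_min
        assert values.max() <= default_config.fat_max

    def test_moments_match_truncated_normal_quadrature(self, default_config, rng):
        """Sample mean/SD agree with truncated-normal moments computed by
        direct numerical integration of the density (location solved by
        bisection so the truncated mean hits the configured target)."""
        cfg = default_config
        a, b, sd = cfg.fat_min, cfg.fat_max, cfg.fat_sd

        def trunc_moments(mu):
            phi = lambda x: np.exp(-0.5 * ((x - mu) / sd) ** 2)
            z, _ = integrate.quad(phi, a, b)
            m1, _ = integrate.quad(lambda x: x * phi(x), a, b)
            m2, _ = integrate.quad(lambda x: x**2 * phi(x), a, b)
            mean = m1 / z
            return mean, np.sqrt(m2 / z - mean**2)

        # oracle location by bisection on the quadrature mean
        lo, hi = a - 5 * sd, b + 5 * sd
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if trunc_moments(mid)[0] < cfg.fat_mean:
                lo = mid
            else:
                hi = mid
        true_mean, true_sd = trunc_moments(0.5 * (lo + hi))

        values = sample_fat_values(10_000, cfg, rng)
        assert values.mean() == pytest.approx(true_mean, abs=0.5)
        assert values.std(ddof=1) == pytest.approx(true_sd, abs=0.5)
        # the truncated mean is the assayed one
        assert values.mean() == pytest.approx(54.63, abs=0.5)


class TestCleanSpectrum:
    def test_zero_amplitude_bands_leave_background_only(self):
        cfg = GeneratorConfig(
            band_params=(Band(1200.0, 40.0, 0.0, 0.0), Band(1450.0, 55.0, 0.0, 0.0))
        )
        spectrum = synthesize_clean_spectrum(54.63, cfg)
        # background is monotone increasing and featureless: no local maxima
        assert np.all(np.diff(spectrum) > 0)

    def test_empty_band_list_rejected(self):
        cfg = GeneratorConfig()
        cfg.band_params = ()
        with pytest.raises(GeneratorConfigError):
            synthesize_clean_spectrum(54.63, cfg)

    def test_fat_band_peak_position(self, default_config):
        cfg = default_config
        spectrum = synthesize_clean_spectrum(54.63, cfg)
        wl = cfg.wavelengths
        window = (wl >= 1150) & (wl <= 1250)
        peak = wl[window][np.argmax(spectrum[window])]
        assert abs(peak - 1200.0) <= cfg.wavelength_step

    def test_linear_in_fat(self, default_config):
        """The spectrum is affine in fat: a 2-point fit predicts a third."""
        cfg = default_config
        s1 = synthesize_clean_spectrum(45.0, cfg)
        s2 = synthesize_clean_spectrum(65.0, cfg)
        s3 = synthesize_clean_spectrum(55.0, cfg)
        np.testing.assert_allclose(s3, s1 + (s2 - s1) * 0.5, atol=1e-12)

    def test_fat_difference_is_proportional_to_coupled_band(self, default_config):
        cfg = default_config
        diff = synthesize_clean_spectrum(70.0, cfg) - synthesize_clean_spectrum(50.0, cfg)
        wl = cfg.wavelengths
        shape = sum(
            band.fat_amp * 0.2 * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
            for band in cfg.band_params
        )
        np.testing.assert_allclose(diff, shape, atol=1e-12)


class TestStateEffects:
    def test_identity_when_all_effects_off(self, zero_noise_config, rng):
        cfg = zero_noise_config
        spectrum = synthesize_clean_spectrum(54.63, cfg)
        out = apply_state_effects(spectrum, "granules", cfg, rng)
        np.testing.assert_allclose(out, spectrum, atol=1e-14)

    def test_unknown_state_rejected(self, default_config, rng):
        spectrum = synthesize_clean_spectrum(54.63, default_config)
        with pytest.raises(GeneratorConfigError):
            apply_state_effects(spectrum, "powder", default_config, rng)

    def test_mean_absorbance_ordering(self, default_config, rng):
        """Monte-Carlo means reproduce granules > de-shelled > in-shell."""
        cfg = default_config
        spectrum = synthesize_clean_spectrum(54.63, cfg)
        means = {
            state: np.mean(
                [apply_state_effects(spectrum, state, cfg, rng).mean() for _ in range(500)]
            )
            for state in STATES
        }
        assert means["granules"] > means["de_shelled"] > means["in_shell"]

    def test_replicate_variability_ordering(self, default_config, rng):
        """Scan-to-scan SD reproduces in-shell > de-shelled > granules."""
        cfg = default_config
        spectrum = synthesize_clean_spectrum(54.63, cfg)
        sds = {}
        for state in STATES:
            reps = np.array(
                [apply_state_effects(spectrum, state, cfg, rng) for _ in range(500)]
            )
            sds[state] = reps.std(axis=0, ddof=1).mean()
        assert sds["in_shell"] > sds["de_shelled"] > sds["granules"]

    def test_replicate_averaging_reduces_variance(self, default_config, rng):
        """Variance of a k-replicate mean is ~1/k of a single replicate."""
        cfg = default_config
        spectrum = synthesize_clean_spectrum(54.63, cfg)
        wl_idx = 200
        singles = np.array(
            [apply_state_effects(spectrum, "granules", cfg, rng)[wl_idx] for _ in range(3000)]
        )
        triples = np.array(
            [
                np.mean(
                    [
                        apply_state_effects(spectrum, "granules", cfg, rng)[wl_idx]
                        for _ in range(3)
                    ]
                )
                for _ in range(1000)
            ]
        )
        ratio = singles.var(ddof=1) / triples.var(ddof=1)
        assert 2.3 < ratio < 3.9


class TestOutlierInjection:
    def test_zero_counts_leave_dataset_unchanged(self, small_dataset, small_config, rng):
        cfg = small_config
        out, truth = inject_outliers(small_dataset, cfg, rng)
        assert out == small_dataset
        assert truth.true_spectral_outlier_ids == set()
        assert truth.true_chemical_outlier_ids == set()

    def test_counts_recorded_disjoint(self, rng):
        cfg = GeneratorConfig(n_spectral_outliers=2, n_chemical_outliers=3, seed=5)
        dataset, truth = generate_dataset(cfg, "granules")
        assert len(truth.true_spectral_outlier_ids) == 2
        assert len(truth.true_chemical_outlier_ids) == 3
        assert not truth.true_spectral_outlier_ids & truth.true_chemical_outlier_ids
        ids = set(dataset.sample_ids.tolist())
        assert truth.true_spectral_outlier_ids | truth.true_chemical_outlier_ids <= ids

    def test_non_outlier_rows_untouched(self, small_config):
        cfg_clean = GeneratorConfig(**{
            **{k: getattr(small_config, k) for k in small_config.__dataclass_fields__},
        })
        clean, _ = generate_dataset(cfg_clean, "granules")
        fields = {k: getattr(small_config, k) for k in small_config.__dataclass_fields__}
        fields.update(n_spectral_outliers=2, n_chemical_outliers=2)
        corrupted, truth = generate_dataset(GeneratorConfig(**fields), "granules")
        planted = truth.true_spectral_outlier_ids | truth.true_chemical_outlier_ids
        for row, sid in enumerate(clean.sample_ids):
            if int(sid) not in planted:
                np.testing.assert_array_equal(
                    clean.absorbance[row], corrupted.absorbance[row]
                )
                assert clean.reference[row] == corrupted.reference[row]

    def test_nonpositive_magnitude_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(n_spectral_outliers=1, spectral_outlier_magnitude=0.0)
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(n_chemical_outliers=1, chemical_outlier_magnitude=-1.0)


class TestGenerateDataset:
    def test_default_shape(self, granule_dataset):
        assert granule_dataset.absorbance.shape == (210, 651)
        assert granule_dataset.sample_ids[0] == 1
        assert granule_dataset.sample_ids[-1] == 210

    def test_determinism(self, small_config):
        d1, t1 = generate_dataset(small_config, "in_shell")
        d2, t2 = generate_dataset(small_config, "in_shell")
        assert d1 == d2
        assert t1.true_spectral_outlier_ids == t2.true_spectral_outlier_ids

    def test_more_replicates_reduce_deviation_from_clean(self, small_config):
        fields = {k: getattr(small_config, k) for k in small_config.__dataclass_fields__}
        rms = {}
        for k in (1, 3):
            fields["replicate_count"] = k
            cfg = GeneratorConfig(**fields)
            dataset, _ = generate_dataset(cfg, "granules")
            clean = np.array(
                [synthesize_clean_spectrum(f, cfg) for f in dataset.reference]
            )
            sp = cfg.state_params["granules"]
            expected = sp.attenuation * clean + sp.level_shift
            rms[k] = np.sqrt(np.mean((dataset.absorbance - expected) ** 2))
        assert rms[3] < rms[1]

    def test_band_center_absorbance_affine_in_fat_without_noise(self, zero_noise_config):
        cfg = zero_noise_config
        dataset, _ = generate_dataset(cfg, "granules")
        wl_idx = int(np.flatnonzero(cfg.wavelengths == 1200.0)[0])
        a_col = dataset.absorbance[:, wl_idx]
        f = dataset.reference
        slope = (a_col[1] - a_col[0]) / (f[1] - f[0])
        intercept = a_col[0] - slope * f[0]
        np.testing.assert_allclose(a_col, intercept + slope * f, atol=1e-9)

    def test_qualitative_orderings_hold_on_seed_panel(self):
        """Mean-absorbance and variability orderings hold per state on
        every seed in a 20-seed panel (reduced sample count)."""
        for seed in range(1, 21):
            cfg = GeneratorConfig(n_samples=25, seed=seed)
            means, spread = {}, {}
            for state in STATES:
                d, _ = generate_dataset(cfg, state)
                means[state] = d.absorbance.mean()
                # remove per-sample fat signal: SD of detrended rows
                spread[state] = np.mean(
                    np.std(d.absorbance - d.absorbance.mean(axis=0), axis=1, ddof=1)
                )
            assert means["granules"] > means["de_shelled"] > means["in_shell"], seed
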