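import numpy as np
import pytest

from nirfat.simkernel import Band, GeneratorConfig, StateParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A reduced acquisition (40 samples, coarse grid) for fast tests."""
    return GeneratorConfig(
        n_samples=40,
        wavelength_step=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def granule_dataset(default_config):
    """Full-size clean granule dataset (no planted outliers), seed 1."""
    dataset, _ = generate_dataset(default_config, "granules")
    return dataset


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, _ = generate_dataset(small_config, "granules")
    return dataset


@pytest.fixture
def zero_noise_config():
    """All stochastic state effects off: apply_state_effects is identity
    (attenuation 1, no shifts)."""
    quiet = StateParams(
        scatter_sd=0.0, offset_sd=0.0, slope_sd=0.0, attenuation=1.0,
        noise_sd=0.0, level_shift=0.0, heterogeneity_sd=0.0,
    )
    return GeneratorConfig(
        state_params={s: quiet for s in ("in_shell", "de_shelled", "granules")},
        seed=3,
    )
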