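import numpy as np
import pytest

from seedspec.spectra_core import BandGrid, SpectralDataset
from seedspec.synthetic_data import GeneratorConfig, calibrate_separability, generate, preset


@pytest.fixture(scope="session")
def grid5() -> BandGrid:
    return BandGrid((432.0, 500.0, 650.0, 800.0, 1025.0))


def make_separable_dataset(n_per_class: int = 30, n_bands: int = 6) -> SpectralDataset:
    """Two classes at (near-)constant, well-separated reflectance vectors.

    A deterministic 1e-6 jitter keeps within-class covariance non-singular
    (sklearn's LDA cannot factorize an exactly zero scatter matrix); the
    classes remain trivially 100%-separable.
    """
    grid = BandGrid.uniform(432.0, 1025.0, n_bands)
    mean0 = 500.0 + 10.0 * np.arange(n_bands)
    mean1 = 800.0 + 12.0 * np.arange(n_bands)
    n = n_per_class
    jitter = 1e-6 * np.sin(np.arange(2 * n * n_bands)).reshape(2 * n, n_bands)
    refl = np.vstack([np.tile(mean0, (n, 1)), np.tile(mean1, (n, 1))]) + jitter
    return SpectralDataset(
        band_grid=grid,
        object_ids=[f"s-{i:04d}" for i in range(2 * n)],
        subsample_ids=["s"] * (2 * n),
        labels=np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)],
        reflectance=refl,
    )


def make_balanced_dataset(
    n_per_class: int, n_bands: int = 20, rng_seed: int = 0, **overrides
) -> SpectralDataset:
    """Synthetic dataset with exactly n_per_class profiles per class."""
    config = GeneratorConfig(
        subsamples=(("g", n_per_class, 1.0), ("n", n_per_class, 0.0)),
        band_grid=BandGrid.uniform(432.0, 1025.0, n_bands),
        rng_seed=rng_seed,
        **overrides,
    )
    return generate(config)


def exchangeable_config(
    n_profiles: int = 400, n_bands: int = 40, rng_seed: int = 0
) -> GeneratorConfig:
    """Single subsample, rate 0.5, no class effect: labels carry no signal."""
    return GeneratorConfig(
        subsamples=(("x", n_profiles, 0.5),),
        band_grid=BandGrid.uniform(432.0, 1025.0, n_bands),
        class_effect_amplitude=0.0,
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def calibrated_config() -> GeneratorConfig:
    """Variety-1 preset with the class effect bisected to a ~70% ten-fold
    LDA baseline (shared across the acceptance tests; ~5 s once)."""
    return calibrate_separability(preset("variety1", rng_seed=1), 70.0, 3.0)


@pytest.fixture(scope="session")
def calibrated_dataset(calibrated_config) -> SpectralDataset:
    return generate(calibrated_config)
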