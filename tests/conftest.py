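import numpy as np
import pytest

from soilspec.dataset import SpectraSet
from soilspec.synthetic import Band, SyntheticConfig, default_soil_config, generate


def small_soil_config(
    grid_points=240,
    n_per_class=(10, 10, 10),
    noisy_channel_sd=0.0,
    seed=0,
):
    """A 3-class, small-grid analogue of the default generator for fast tests."""
    classes = ("Albic Luvisols", "Haplic Luvisols", "Chernozems")
    library = {
        "Albic Luvisols": (Band(4094.0, 30.0, 0.20, 0.05),),
        "Haplic Luvisols": (Band(5263.0, 30.0, 0.20, 0.05),),
        "Chernozems": (Band(4287.0, 30.0, 0.25, 0.05),),
    }
    quiet = tuple((b.center, 120.0) for bands in library.values() for b in bands)
    quiet += ((5222.0, 120.0),)
    return SyntheticConfig(
        class_names=classes,
        n_per_class=n_per_class,
        grid_points=grid_points,
        shared_bands=(Band(5222.0, 60.0, 0.4, 0.1),),
        band_library=library,
        baseline_intercept_mean={
            "Albic Luvisols": 0.4,
            "Haplic Luvisols": 0.6,
            "Chernozems": 0.9,
        },
        quiet_zones=quiet if noisy_channel_sd > 0 else (),
        noisy_channel_sd=noisy_channel_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_spectra():
    """30 samples x 240 channels, 3 well-separated classes."""
    spectra, _ = generate(small_soil_config(), seed=11)
    return spectra


@pytest.fixture(scope="session")
def study_shaped():
    """Full study-shaped synthetic data: 230 x 1816, 5 classes."""
    spectra, truth = generate(default_soil_config(), seed=7)
    return spectra, truth


@pytest.fixture
def tiny_spectra():
    """Deterministic 9-sample, 5-feature, 3-class set for brute-force oracles."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(9, 5))
    labels = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
    X[:3, 0] += 2.0
    X[3:6, 1] += 2.0
    X[6:, 2] += 2.0
    wn = np.linspace(5000.0, 4000.0, 5)
    ids = [f"t{i}" for i in range(9)]
    return SpectraSet(wn, X, ids, labels, ("A", "B", "C"))
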