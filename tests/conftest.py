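import numpy as np
import pytest

from h2dcos import GeneratorConfig, SpectrumSet, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced study design: coarse grids, 3 plants per cell, one band each."""
    return GeneratorConfig(
        n_plants_per_cell=3,
        micro_grid=np.arange(400.0, 1000.0 + 1e-9, 8.0),
        macro_grid=np.arange(400.0, 1000.0 + 1e-9, 9.4),
        sensitive_bands_micro=(547.0,),
        sensitive_bands_macro=(607.0,),
        n_cubes=1,
        cube_shape=(8, 8),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def spectrum_set():
    """Hand-sized SpectrumSet for operator-level tests."""
    rng = np.random.default_rng(5)
    wl = np.arange(500.0, 560.0, 4.0)
    return SpectrumSet(
        ids=np.array([f"s{i}" for i in range(6)], dtype=object),
        X=rng.normal(size=(6, wl.size)),
        wavelengths=wl,
        perturbation=np.linspace(0.1, 0.3, 6),
        modality="micro",
    )
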