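import numpy as np
import pytest

from mammo_qwtapcnn import synth_io


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def benign_phantom():
    return synth_io.generate_phantom(label="benign", seed=5)


@pytest.fixture(scope="session")
def malignant_phantom():
    return synth_io.generate_phantom(label="malignant", seed=5)


@pytest.fixture(scope="session")
def normal_phantom():
    return synth_io.generate_phantom(label="normal", seed=5)


@pytest.fixture(scope="session")
def two_intensity_phantom():
    """Mass at 200 on uniform 120 tissue filling the frame (no background)."""
    return synth_io.generate_phantom(
        label="benign", seed=7,
        background_level=120.0, tissue_level=120.0, texture_sigma=0.0,
        breast_axes=(400.0, 400.0),
        mass_params=synth_io.MassParams(center=(128, 128), radius=20, contrast=80),
    )
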