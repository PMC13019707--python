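import numpy as np
import pytest

from vibroelast import (
    GridSpec,
    SourcePlacementSpec,
    make_synthetic_dataset,
)
from vibroelast.patches import PatchSample


@pytest.fixture(scope="session")
def patch_grid() -> GridSpec:
    return GridSpec(71, 11)


@pytest.fixture(scope="session")
def binary_dataset():
    """Clean synthetic binary dataset at the canonical per-class size."""
    return make_synthetic_dataset(
        (1.0, 5.0), 52, SourcePlacementSpec(), GridSpec(71, 11), seed=123
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def plane_wave_patch() -> PatchSample:
    """A pure plane wave along the 71-point axis with a 4 mm wavelength."""
    y = 0.5e-3 * np.arange(71)
    k = 2 * np.pi / 4e-3
    field = np.exp(-1j * k * y)[:, None] * np.ones((1, 11))
    values = np.stack([field.real, field.imag], axis=-1)
    return PatchSample(values, 0, {"origin": "plane-wave"})
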