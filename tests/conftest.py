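import numpy as np
import pytest

from petstage.io_volumes import PetCtVolume
from petstage.phantom import PhantomConfig, generate_subject


def make_volume(pet, ct=None, spacing=(3.0, 3.0, 3.0), origin=(0.0, 0.0, 0.0)):
    pet = np.asarray(pet, dtype=np.float32)
    if ct is None:
        ct = np.zeros_like(pet)
    return PetCtVolume(pet=pet, ct=np.asarray(ct, dtype=np.float32),
                       spacing=np.asarray(spacing), origin=np.asarray(origin))


def gaussian_blob(shape, center, sigma, peak):
    """Isotropic Gaussian uptake blob on a zero background."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return peak * np.exp(-d2 / (2.0 * sigma**2))


@pytest.fixture(scope="session")
def phantom_subject():
    """One deterministic phantom with lesions of three classes."""
    cfg = PhantomConfig(
        tracer="PSMA",
        lesion_counts={"regional_node": 1, "bone": 2, "other_organ": 1},
        seed=42,
    )
    return generate_subject(cfg)


@pytest.fixture(scope="session")
def lesion_free_subject():
    return generate_subject(PhantomConfig(tracer="PSMA", seed=7))
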