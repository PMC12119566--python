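"""Shared fixtures: small phantoms and datasets generated at test time."""

import numpy as np
import pytest

from cardseg.phantom import PhantomSpec, generate_phantom


SMALL_SPEC = PhantomSpec(
    grid_shape=(24, 24, 20),
    chamber_semi_axes=(6.0, 5.0, 4.0),
    n_appendages=2,
    appendage_radius=1.5,
    noise_sigma=0.05,
    bias_field_strength=0.15,
    seed=11,
)


@pytest.fixture(scope="session")
def small_phantom():
    """One 24x24x20 phantom (volume, label) with mild noise and bias."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
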