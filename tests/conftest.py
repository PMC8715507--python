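import numpy as np
import pytest

from jchi.karplus import FourierCoefficients
from jchi.synth import demo_karplus_set


@pytest.fixture(scope="session")
def val_kset():
    return demo_karplus_set("VAL")


@pytest.fixture(scope="session")
def leu_kset():
    return demo_karplus_set("LEU")


@pytest.fixture(scope="session")
def ile_kset():
    return demo_karplus_set("ILE")


def random_coefficients(rng, scale=5.0, **metadata) -> FourierCoefficients:
    return FourierCoefficients.from_array(
        rng.uniform(-scale, scale, size=6), **metadata
    )


def karplus_like_coefficients(rng) -> FourierCoefficients:
    """Random coefficients shaped like a proton-proton Karplus curve:
    dominant cos2 term, moderate negative cos term, small others."""
    return FourierCoefficients(
        c0=rng.uniform(4, 8),
        c1=rng.uniform(-2, -0.5),
        c2=rng.uniform(3.5, 6),
        c3=rng.uniform(-0.3, 0.3),
        s1=rng.uniform(-0.2, 0.2),
        s2=rng.uniform(-0.2, 0.2),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210773)
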