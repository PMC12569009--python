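import numpy as np
import pytest

from lensulm.arrays import (
    ElementSpec,
    LensSpec,
    build_multilens_array,
    central_transmit_indices,
    multilens_252,
)


@pytest.fixture(scope="session")
def full_layout():
    """The 252-element lensed profile."""
    return multilens_252()


@pytest.fixture(scope="session")
def single_lensed():
    return build_multilens_array(1, 1, 5.48, ElementSpec(), LensSpec())


@pytest.fixture(scope="session")
def single_unlensed():
    return build_multilens_array(1, 1, 5.48, ElementSpec(), None)


@pytest.fixture(scope="session")
def single_small():
    lam = ElementSpec().wavelength_mm
    el = ElementSpec(width_lateral=lam / 2, width_elevational=lam / 2)
    return build_multilens_array(1, 1, lam, el, None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sixteen_source_indices():
    return central_transmit_indices(18, 14, 4)
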