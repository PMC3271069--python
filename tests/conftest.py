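import numpy as np
import pytest

from ecomics.bmchar import load_default_roi_database
from ecomics.fixtures import AxisSpec, gen_spectrum


@pytest.fixture(scope="session")
def roi_db():
    return load_default_roi_database()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def spectrum_1d():
    """A small noiseless 1D spectrum with three well-separated peaks."""
    return gen_spectrum(
        [(1.2, 5.0, 0.05), (3.7, 2.0, 0.05), (7.3, 1.0, 0.08)],
        AxisSpec(-1.0, 9.0, 512),
        seed=7,
        label="demo",
    )
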