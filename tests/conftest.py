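import numpy as np
import pytest

from gietkit import build_curve


@pytest.fixture(scope="session")
def fam_curve():
    return build_curve("FAM", d_min=2.5, d_max=30.0, step=0.05)


@pytest.fixture(scope="session")
def egfp_curve():
    return build_curve("EGFP", d_min=2.5, d_max=30.0, step=0.05)


@pytest.fixture(scope="session")
def dy647_curve():
    return build_curve("Dy647P1", d_min=2.5, d_max=30.0, step=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
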