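import numpy as np
import pytest

import sspca


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def single_factor_80x20(rng):
    """One (80, 20) draw from the single-factor model plus its truth."""
    scen = sspca.SimScenario(n=80, p=20, beta_sq=2.0, phi=0.1)
    X, truth = sspca.generate(scen, rng)
    return sspca.center_columns(X), truth, scen


@pytest.fixture
def wide_matrix(rng):
    """A generic (50, 200) centered matrix (p > n path)."""
    return sspca.center_columns(rng.standard_normal((50, 200)))
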