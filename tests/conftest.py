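import numpy as np
import pandas as pd
import pytest

from deltalcs import bivariate_config, bivariate_lcs_spec, generate_longitudinal


@pytest.fixture(scope="session")
def biv_spec():
    return bivariate_lcs_spec()


@pytest.fixture(scope="session")
def small_cohort():
    """One longitudinal cohort at the calibrated study parameters."""
    return generate_longitudinal(bivariate_config(seed=42), 653)


@pytest.fixture(scope="session")
def toy_bivariate_data():
    """Tiny 2-variable Gaussian sample for hand-checked moments."""
    rng = np.random.default_rng(7)
    x = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 1.5]], size=40)
    return pd.DataFrame(x, columns=["x1", "x2"])
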