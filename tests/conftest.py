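import numpy as np
import pytest

from mssr.conditions import Complexity, ConditionSpec
from mssr.dgp import CoefficientSet, SimulatedDataset, generate_dataset
from mssr.fixtures import EQ10_CONDITION, eq10_coefficients


@pytest.fixture(scope="session")
def cond_medium3():
    """Medium-complexity 3-IV cell with small linear / large nonlinear
    coefficients at error level 1 (the cell whose coefficients are
    printed in full in the published study)."""
    return EQ10_CONDITION


@pytest.fixture(scope="session")
def eq10():
    return eq10_coefficients()


@pytest.fixture(scope="session")
def eq10_noiseless():
    return eq10_coefficients(coferr=0.0)


@pytest.fixture(scope="session")
def linear_condition():
    """Simple-complexity 3-IV cell used for near-linear sanity datasets."""
    return ConditionSpec(
        complexity=Complexity.SIMPLE, n_iv=3,
        linear_level="large", nonlinear_level="small", error_coef=1.0,
    )


@pytest.fixture(scope="session")
def noiseless_linear_dataset(linear_condition):
    """n=2000 dataset whose outcome is an exact linear function of the
    *observed* Likert codes: a network that can represent a linear map
    should reach near-perfect test R² here (no attenuation gap, unlike
    outcomes generated from the latent scores)."""
    coefs = CoefficientSet(cof=(0.9, 0.7, 0.8), conf=(0.0, 0.0), coferr=0.0)
    ds = generate_dataset(linear_condition, 2000, coefs, seed=321)
    y = ds.X @ np.array([0.9, 0.7, 0.8])
    return SimulatedDataset(X=ds.X, Y=y, latent=ds.latent,
                            condition=ds.condition, coefficients=coefs, seed=321)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
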