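import numpy as np
import pytest

from qpopkit.design import DrugDoseSpec, compose_oacd
from qpopkit.qpop import QuadraticSurface
from qpopkit.simulate import dose_specs_from_panel


@pytest.fixture(scope="session")
def oacd9():
    return compose_oacd(9)


@pytest.fixture(scope="session")
def specs9():
    return dose_specs_from_panel()


@pytest.fixture(scope="session")
def random_surface9():
    """A fixed random 55-coefficient surface over nine coded factors."""
    rng = np.random.default_rng(2024)
    return QuadraticSurface(
        n_factors=9,
        beta0=float(rng.normal()),
        beta_lin=rng.normal(size=9),
        beta_quad=rng.normal(size=9),
        beta_int=rng.normal(size=36),
        adj_r2=1.0,
        f_stat=np.nan,
        f_pvalue=np.nan,
        residual_ss=0.0,
        df_resid=0,
    )


def make_specs(names, low=0.0, mid=1.0, high=2.0):
    return [
        DrugDoseSpec(drug_name=n, conc_at_level={-1: low, 0: mid, 1: high})
        for n in names
    ]
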