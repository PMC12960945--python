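import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rangesweep.analytic import MacroParams
from rangesweep.poisson import effective_mutation_rate

#: the validation-study defaults: c_wt=0.15, c_m=0.31, mu_tilde=1e-5, rho=0.23
DEFAULT_MU = effective_mutation_rate(1e-5, 0.23)


@pytest.fixture(scope="session")
def params3d() -> MacroParams:
    return MacroParams(c_wt=0.15, c_m=0.31, mu=DEFAULT_MU, d=3)


@pytest.fixture(params=[1, 2, 3], ids=["d1", "d2", "d3"])
def params_any_d(request) -> MacroParams:
    return MacroParams(c_wt=0.15, c_m=0.31, mu=DEFAULT_MU, d=request.param)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
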