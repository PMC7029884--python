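import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from rheofract import FractionalModelParams


@pytest.fixture
def full_model() -> FractionalModelParams:
    """Monolayer-scale full model: tau1 ~ 10 s, tau2 = 10 s, xi ~ 1."""
    return FractionalModelParams(c_beta=200.0, beta=0.3, eta=1000.0, k=100.0)


@pytest.fixture
def sls_model() -> FractionalModelParams:
    return FractionalModelParams.standard_linear_solid(c=200.0, eta=1000.0, k=100.0)


@pytest.fixture
def spring_pot_model() -> FractionalModelParams:
    return FractionalModelParams.spring_pot(c_beta=100.0, beta=0.4)


@pytest.fixture
def fmm_model() -> FractionalModelParams:
    return FractionalModelParams.fractional_maxwell(c_beta=200.0, beta=0.3, eta=1000.0)


def random_params(rng: np.random.Generator) -> FractionalModelParams:
    """Random draw over the physically plausible parameter box."""
    return FractionalModelParams(
        c_beta=float(10.0 ** rng.uniform(0.5, 3.0)),
        beta=float(rng.uniform(0.05, 0.8)),
        eta=float(10.0 ** rng.uniform(1.5, 4.0)),
        k=float(10.0 ** rng.uniform(0.5, 2.5)),
    )
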