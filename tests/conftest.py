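import math

import numpy as np
import pytest
from hypothesis import settings

from gridcog import FiringParams, GridCell, build_environment

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def eq_cell() -> GridCell:
    """The single-cell experiment's grid cell: spacing 1, orientation pi/4,
    phase (0.5, 0)."""
    return GridCell(1.0, math.pi / 4, (0.5, 0.0))


@pytest.fixture(scope="session")
def fparams() -> FiringParams:
    return FiringParams(zeta=0.4, kappa=3.0)


@pytest.fixture(scope="session")
def square5():
    return build_environment("square", side=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
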