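import numpy as np
import pytest

from fluxbind.ensembles import BasinSpec
from fluxbind.toy_system import ToySystemParams
from fluxbind.units import UnitsContext


@pytest.fixture
def units300():
    return UnitsContext(temperature=300.0)


@pytest.fixture
def fast_params():
    """Fast toy parameterization: shallow wide well, like charges,
    paper-sized box, 10 fs timestep so rare events happen at desk scale."""
    return ToySystemParams(well_depth=4.0, well_width=0.2, timestep=0.01,
                           friction=1.0)


@pytest.fixture
def basin():
    return BasinSpec(bound_cutoff=0.1, unbound_cutoff=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
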