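import numpy as np
import pytest

from aerowalk.flow_fields import (
    AIR,
    FlowSample,
    make_analytic_pipe_field,
)

#: Benchmark pipe: 1.27 cm bore, 102 cm long, 86.36 L/min, nominal Re 10,000.
PIPE_DIAMETER = 0.0127
PIPE_LENGTH = 1.02
PIPE_FLOW_RATE = 86.36e-3 / 60.0
PIPE_REYNOLDS = 10_000.0


@pytest.fixture(scope="session")
def pipe_field():
    return make_analytic_pipe_field(
        PIPE_DIAMETER,
        flow_rate=PIPE_FLOW_RATE,
        reynolds=PIPE_REYNOLDS,
        length=PIPE_LENGTH,
    )


@pytest.fixture()
def uniform_sample():
    """Homogeneous-turbulence sample far from any wall."""
    return FlowSample(
        mean_velocity=np.zeros(3),
        tke=0.15,
        sdr=5.0,
        wall_distance=1.0,
        wall_normal=np.array([0.0, 0.0, 1.0]),
        friction_velocity=0.0,
        fluid_density=AIR.density,
        dynamic_viscosity=AIR.viscosity,
    )
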