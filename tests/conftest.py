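import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from straincycle import (
    Condition,
    CycleParams,
    FieldParams,
    ImagingParams,
    initialize_quiescent_monolayer,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_field():
    """A small (fast) monolayer field: ~25 cells on 160x160 um."""
    return FieldParams(width_um=160.0, height_um=160.0, maturation_hours=24.0)


@pytest.fixture
def small_state(small_field):
    return initialize_quiescent_monolayer(seed=11, field_params=small_field)


@pytest.fixture
def imaging():
    return ImagingParams()


@pytest.fixture
def frozen_params():
    """Degenerate kinetics: no hazards, closed gates, infinite dwell times."""
    return CycleParams(
        basal_exit_rate=0.0,
        strain_exit_rate=0.0,
        mitotic_rate=0.0,
        requiescence_rate=0.0,
        theta1=np.inf,
        theta2=np.inf,
        s_duration_h=np.inf,
        jitter_um=0.0,
    )
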