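import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def simple_trial():
    """Hand-constructed two-stride trial used across modules.

    Left heel strikes at 0/1/2 s, right in perfect anti-phase at 0.5/1.5 s,
    all swing times 0.38 s.
    """
    from gaitcoord import GaitEventSeries

    return GaitEventSeries(
        subject_id="demo",
        condition="usual",
        belt_speed=1.0,
        left_hs=[0.0, 1.0, 2.0],
        left_to=[0.62, 1.62],
        right_hs=[0.5, 1.5],
        right_to=[0.12, 1.12],
    )
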