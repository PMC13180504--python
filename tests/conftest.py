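import numpy as np
import pytest
from hypothesis import settings

from rmstdesign import ArmModel, ScenarioSpec

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def ph_scenario():
    """Proportional-hazards world: exponential arms, HR = 1/1.7."""
    return ScenarioSpec(
        experimental=ArmModel("exponential", lam0=0.9),
        control=ArmModel("exponential", lam0=0.9 * 1.7),
        accrual_rate=60,
        min_followup=1.0,
        tau=2.5,
    )


@pytest.fixture
def late_diff_scenario():
    """Late-difference world: HR 1 before 0.5 y, 0.45 after."""
    return ScenarioSpec(
        experimental=ArmModel(
            "piecewise_exponential", lam0=1.0, delta1=1.0, delta2=0.45, change_time=0.5
        ),
        control=ArmModel("exponential", lam0=1.0),
        accrual_rate=120,
        min_followup=1.0,
        tau=3.0,
    )
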