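import numpy as np
import pytest

from oxydeficit.trace_synth import BreathPlan, synthesize_trace


@pytest.fixture
def quiet_plan() -> BreathPlan:
    """Noiseless, artifact-free 15 breaths/min plan."""
    return BreathPlan(
        respiratory_rate=15.0,
        et_po2=105.0,
        et_pco2=36.0,
        plateau_noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def quiet_trace(quiet_plan):
    return synthesize_trace(quiet_plan, 60.0)


@pytest.fixture
def cough_plan() -> BreathPlan:
    """Short trace with a cough in the second breath; no trailing 45 s of
    clean breaths exists, so steady state is never achieved."""
    return BreathPlan(respiratory_rate=15.0, cough_times=(6.5,), seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
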