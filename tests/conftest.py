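import numpy as np
import pytest

from hoverstab.synthetic import MotionParams, SyntheticPlan, TraceParams


@pytest.fixture
def noiseless_plan() -> SyntheticPlan:
    """Thirteen species, exact linear responses, quiet traces."""
    return SyntheticPlan(
        seed=1,
        noise_sd=0.0,
        ratio_noise_sd=0.0,
        trace_params=TraceParams(noise_sd=0.0),
    )


@pytest.fixture
def still_series():
    """Landmark series with no body wobble (pure fin strokes)."""
    from hoverstab.synthetic import gen_landmark_series

    plan = SyntheticPlan(
        seed=4,
        motion_params=MotionParams(roll_amp_deg=0.0, pitch_amp_deg=0.0),
    )
    series, truth = gen_landmark_series(plan)
    return series, truth


@pytest.fixture
def sine_pair():
    """2 Hz sinusoid sampled at 1000 fps for 3 s, endpoint included."""
    t = np.arange(0, 3 + 1e-9, 1 / 1000.0)
    return t, np.sin(2 * np.pi * 2 * t)
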