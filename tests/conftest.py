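import numpy as np
import pytest

from petgfr import (
    InputFunctionParams,
    KidneyTruth,
    make_frame_schedule,
    simulate_plasma_input,
    to_plasma,
)
from petgfr.frames import DEFAULT_SCHEDULE_SPEC


@pytest.fixture(scope="session")
def clinical_schedule():
    """The 72-frame 30-min protocol: 24x5 s, 18x10 s, 10x30 s, 20x60 s."""
    return make_frame_schedule(DEFAULT_SCHEDULE_SPEC)


@pytest.fixture(scope="session")
def input_params():
    return InputFunctionParams()


@pytest.fixture(scope="session")
def aorta_curve(clinical_schedule, input_params):
    """Noise-free whole-blood aortic input on the clinical frame schedule."""
    return simulate_plasma_input(input_params, clinical_schedule)


@pytest.fixture(scope="session")
def plasma_curve(aorta_curve):
    """Plasma input for haematocrit 0.35."""
    return to_plasma(aorta_curve, 0.35)


@pytest.fixture(scope="session")
def default_truth():
    return KidneyTruth(
        k1_per_min=0.3, k2_per_min=0.08, vb=0.2, v_rc_ml=140.0,
        spill_fraction=0.0, spill_delay_s=60.0,
    )
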