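import numpy as np
import pandas as pd
import pytest

from hctsens import EffectEstimate, ScenarioConfig, generate_replicate


@pytest.fixture
def asthma_medium():
    """Summary estimates of the medium-dose dual-therapy hybrid trial."""
    return {
        "hct": EffectEstimate(0.81, 0.70, 0.94, kind="hct_effect"),
        "trial": EffectEstimate(0.92, 0.77, 1.10, kind="trial_effect"),
        "rd": EffectEstimate(0.79, 0.67, 0.92, kind="residual_difference"),
        "eta": 1.0,
    }


@pytest.fixture
def asthma_high():
    """Summary estimates of the high-dose triple-therapy hybrid trial."""
    return {
        "hct": EffectEstimate(0.65, 0.54, 0.76, kind="hct_effect"),
        "trial": EffectEstimate(0.73, 0.60, 0.89, kind="trial_effect"),
        "rd": EffectEstimate(0.79, 0.67, 0.92, kind="residual_difference"),
        "eta": 1.0,
    }


@pytest.fixture
def small_cfg():
    """A fast scenario for smoke-level simulation tests."""
    return ScenarioConfig(rr_su=1.5, rr_ay=1.0, eta=2.0, n_reps=50, seed=123)


@pytest.fixture
def subject_table():
    """One simulated replicate under the default study conditions."""
    return generate_replicate(ScenarioConfig(seed=11), rep=0)
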