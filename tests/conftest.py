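import numpy as np
import pytest

from rewardseek import synth

FOOD_MIX = {
    "cue_activated": 0.2,
    "cue_inhibited": 0.2,
    "reward_activated": 0.2,
    "reward_inhibited": 0.2,
    "nonencoding": 0.2,
}
DRUG_MIX = {
    "cue_activated": 0.2667,
    "reward_activated": 0.2667,
    "press_inhibited": 0.2666,
    "nonencoding": 0.2,
}


@pytest.fixture(scope="session")
def pr_events():
    """30 regularly spaced cue/reward trials."""
    return synth.pr_like_events(30)


@pytest.fixture(scope="session")
def food_session(pr_events):
    spec = synth.SpikeGenSpec(n_units=150, profile_mix=FOOD_MIX, seed=1)
    return synth.gen_spike_session(spec, pr_events)
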