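import numpy as np
import pandas as pd
import pytest

from trialhist import synthetic
from trialhist.io import TRIAL_COLUMNS


@pytest.fixture
def task_cfg():
    return synthetic.TaskConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trials(
    n=20,
    session_id="s0",
    mouse_id="m0",
    odor=0.8,
    choice="L",
    rewarded=1.0,
    condition="baseline",
    trial_gap=3.0,
):
    """Hand-built trial table with simple deterministic timing."""
    starts = np.arange(n, dtype=float) * trial_gap
    df = pd.DataFrame(
        {
            "session_id": session_id,
            "mouse_id": mouse_id,
            "trial_index": np.arange(n),
            "odor_port_entry": starts,
            "valve_open": starts + 0.144,
            "go": starts + 0.6,
            "odor_port_exit": starts + 0.8,
            "reward_port_entry": starts + 1.1,
            "reward_port_exit": starts + 2.1,
            "odor_left_fraction": odor,
            "choice": choice,
            "rewarded": rewarded,
            "condition": condition,
        }
    )
    return df[TRIAL_COLUMNS]


@pytest.fixture
def simple_trials():
    return make_trials()


@pytest.fixture
def session_with_unit():
    """A simulated session with one previous-choice-modulated unit."""
    cfg = synthetic.TaskConfig()
    params = synthetic.BehaviorParams(beta_choice=(0.7,))
    neuron = synthetic.NeuronParams(
        unit_id="u0",
        baseline_rate=10.0,
        modulation_terms=(
            synthetic.Modulation("prev_choice", 5.0, "odor_port_entry", (-0.05, 0.30)),
        ),
    )
    return synthetic.simulate_session(cfg, params, [neuron], seed=7, n_trials=300)
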