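import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from infobias import agents, generate_session
from infobias.models import ModelParams
from infobias.schedule import BlockSpec, BlockType, OutcomeSchedule


@pytest.fixture(scope="session")
def session_schedule():
    return generate_session("win_volatile_first", 1234)


@pytest.fixture(scope="session")
def m1_params():
    return ModelParams(alpha_win=0.4, alpha_loss=0.15, beta_win=6.0, beta_loss=5.0)


@pytest.fixture(scope="session")
def m1_session(session_schedule, m1_params):
    """One simulated participant under the primary model."""
    return agents.simulate_agent(
        "m1", m1_params, session_schedule, seed=99, participant_id=1
    )


def make_schedule(win_on_A, loss_on_A, p_win=None, p_loss=None):
    """Hand-built realised schedule from outcome indicator lists."""
    n = len(win_on_A)
    return OutcomeSchedule(
        p_win_A=np.asarray(p_win if p_win is not None else [np.nan] * n, float),
        p_loss_A=np.asarray(p_loss if p_loss is not None else [np.nan] * n, float),
        win_side=np.where(np.asarray(win_on_A) == 1, "A", "B"),
        loss_side=np.where(np.asarray(loss_on_A) == 1, "A", "B"),
    )


@pytest.fixture
def hand_schedule():
    """5-trial schedule used by the hand-iterated recursion checks."""
    return make_schedule(
        win_on_A=[1, 0, 1, 1, 0], loss_on_A=[0, 1, 0, 0, 1]
    )
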