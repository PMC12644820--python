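import numpy as np
import pytest

from qreplay.agent import ARMS, AgentParams
from qreplay.behavior import BehaviorDataset, TrialRecord


def make_trials(triples, session_length=None, stage="initial", rat_id="r1"):
    """Build TrialRecords from (state, action, reward) triples.

    ``triples`` uses arm names or indices; sessions are cut every
    ``session_length`` trials (one session if None).
    """
    out = []
    for k, (s, a, r) in enumerate(triples, start=1):
        s = ARMS[s] if isinstance(s, int) else s
        a = ARMS[a] if isinstance(a, int) else a
        session = 1 if session_length is None else 1 + (k - 1) // session_length
        out.append(
            TrialRecord(
                rat_id=rat_id,
                session=session,
                trial_index=k,
                state=s,
                action=a,
                reward=int(r),
                legitimate=s != a,
                stage=stage,
            )
        )
    return out


def make_dataset(triples, session_length=None, stage="initial", rat_id="r1"):
    return BehaviorDataset(make_trials(triples, session_length, stage, rat_id))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return AgentParams(alpha=0.1, gamma=0.9, epsilon=2.0, phi=1.0, psi=1.1)
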