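"""Ground-truth behavioural generator: a Q-learning agent (optionally with
between-session replay) foraging on the staged three-arm maze.

Reward delivery defaults to quota mode: every block of 8 legitimate entries
to an arm contains exactly the stage's numerator of rewards (6/8 on the
initial high arm, etc.), with the rewarded slots shuffled within the block.
Independent-Bernoulli delivery is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..agent import ARMS, AgentParams, action_probabilities, arm_index, compute_rpe, init_q, q_update
from ..behavior import BehaviorDataset, TrialRecord
from ..replay import ReplayBuffer, ReplayConfig, replay_batch

__all__ = [
    "Stage",
    "TaskSchedule",
    "default_schedule",
    "ephys_schedule",
    "generate_behavior",
    "random_behavior",
]

BLOCK = 8  # quota block length (probabilities are multiples of 1/8)


@dataclass(frozen=True)
class Stage:
    name: str
    n_sessions: int
    probs: Dict[str, float]

    def __post_init__(self):
        for arm, p in self.probs.items():
            if Fraction(p).limit_denominator(BLOCK) * BLOCK % 1 != 0:
                raise ValueError(f"reward probability {p} for {arm} is not a multiple of 1/{BLOCK}")


@dataclass
class TaskSchedule:
    stages: List[Stage]
    delivery: str = "quota"  # "quota" | "bernoulli"

    def __post_init__(self):
        if self.delivery not in ("quota", "bernoulli"):
            raise ValueError("delivery must be 'quota' or 'bernoulli'")

    @property
    def n_sessions(self) -> int:
        return sum(s.n_sessions for s in self.stages)

    def stage_of_session(self, session: int) -> Stage:
        acc = 0
        for s in self.stages:
            acc += s.n_sessions
            if session <= acc:
                return s
        raise ValueError(f"session {session} beyond schedule ({self.n_sessions} sessions)")

    def stage_probs(self) -> Dict[str, Dict[str, float]]:
        return {s.name: dict(s.probs) for s in self.stages}


def default_schedule(
    n_initial: int = 15, n_revaluation: int = 5, n_reversal: int = 2, delivery: str = "quota"
) -> TaskSchedule:
    """Behavioural-cohort schedule: 75/50/25 -> 87.5/50/12.5 -> reversed."""
    return TaskSchedule(
        stages=[
            Stage("initial", n_initial, {"high": 0.75, "mid": 0.50, "low": 0.25}),
            Stage("revaluation", n_revaluation, {"high": 0.875, "mid": 0.50, "low": 0.125}),
            Stage("reversal", n_reversal, {"high": 0.125, "mid": 0.50, "low": 0.875}),
        ],
        delivery=delivery,
    )


def ephys_schedule(n_initial: int = 13, n_reversal: int = 5, delivery: str = "quota") -> TaskSchedule:
    """Recorded-cohort schedule: 87.5/50/12.5 then reversed."""
    return TaskSchedule(
        stages=[
            Stage("initial", n_initial, {"high": 0.875, "mid": 0.50, "low": 0.125}),
            Stage("reversal", n_reversal, {"high": 0.125, "mid": 0.50, "low": 0.875}),
        ],
        delivery=delivery,
    )


class _QuotaDispenser:
    """Delivers exactly k rewards per shuffled block of 8 legitimate entries."""

    def __init__(self, prob: float, rng: np.random.Generator):
        self.k = int(round(prob * BLOCK))
        self.rng = rng
        self.queue: List[int] = []

    def draw(self) -> int:
        if not self.queue:
            block = [1] * self.k + [0] * (BLOCK - self.k)
            self.rng.shuffle(block)
            self.queue = block
        return self.queue.pop()


def generate_behavior(
    params: AgentParams,
    schedule: Optional[TaskSchedule] = None,
    trials_per_session: int = 45,
    seed: int = 0,
    replay: Optional[ReplayConfig] = None,
    rat_id: str = "sim",
    start_arm: str = "high",
) -> Tuple[BehaviorDataset, Dict]:
    """Simulate one rat; returns (dataset, ground_truth).

    ``ground_truth`` records the generating parameters, replay config and
    the agent's Q table at every session boundary.
    """
    schedule = schedule or default_schedule()
    replay = replay or ReplayConfig()
    rng = np.random.default_rng(seed)
    q = init_q()
    buffer = ReplayBuffer()
    trials: List[TrialRecord] = []
    q_trajectory = [q.copy()]

    state = arm_index(start_arm)
    k = 0
    stage_dispensers: Dict[Tuple[str, str], _QuotaDispenser] = {}
    for session in range(1, schedule.n_sessions + 1):
        stage = schedule.stage_of_session(session)
        if session > 1 and replay.policy != "none" and replay.n_replay > 0:
            q = replay_batch(q, buffer, replay, params, rng)
        for _ in range(trials_per_session):
            k += 1
            p = action_probabilities(q, state, params.epsilon)
            action = int(rng.choice(3, p=p))
            legitimate = action != state
            if not legitimate:
                reward = 0
            elif schedule.delivery == "bernoulli":
                reward = int(rng.random() < stage.probs[ARMS[action]])
            else:
                key = (stage.name, ARMS[action])
                if key not in stage_dispensers:
                    stage_dispensers[key] = _QuotaDispenser(stage.probs[ARMS[action]], rng)
                reward = stage_dispensers[key].draw()
            trials.append(
                TrialRecord(
                    rat_id=rat_id,
                    session=session,
                    trial_index=k,
                    state=ARMS[state],
                    action=ARMS[action],
                    reward=reward,
                    legitimate=legitimate,
                    stage=stage.name,
                )
            )
            next_state = action
            delta = compute_rpe(q, state, action, reward, next_state, params.gamma)
            buffer.add(state, action, reward, delta)
            q = q_update(q, state, action, reward, next_state, params.alpha, params.gamma)
            state = next_state
        q_trajectory.append(q.copy())

    dataset = BehaviorDataset(trials, rat_id=rat_id, schedule=schedule.stage_probs())
    truth = {
        "params": params,
        "replay": replay,
        "seed": seed,
        "q_trajectory": q_trajectory,
        "schedule": schedule,
    }
    return dataset, truth


def random_behavior(
    schedule: Optional[TaskSchedule] = None,
    trials_per_session: int = 45,
    seed: int = 0,
    rat_id: str = "null",
    start_arm: str = "high",
) -> BehaviorDataset:
    """Non-learning uniform-random behaver: a null generator independent of
    the agent code under test."""
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    trials: List[TrialRecord] = []
    state = arm_index(start_arm)
    dispensers: Dict[Tuple[str, str], _QuotaDispenser] = {}
    k = 0
    for session in range(1, schedule.n_sessions + 1):
        stage = schedule.stage_of_session(session)
        for _ in range(trials_per_session):
            k += 1
            action = int(rng.integers(3))
            legitimate = action != state
            if not legitimate:
                reward = 0
            elif schedule.delivery == "bernoulli":
                reward = int(rng.random() < stage.probs[ARMS[action]])
            else:
                key = (stage.name, ARMS[action])
                if key not in dispensers:
                    dispensers[key] = _QuotaDispenser(stage.probs[ARMS[action]], rng)
                reward = dispensers[key].draw()
            trials.append(
                TrialRecord(
                    rat_id=rat_id,
                    session=session,
                    trial_index=k,
                    state=ARMS[state],
                    action=ARMS[action],
                    reward=reward,
                    legitimate=legitimate,
                    stage=stage.name,
                )
            )
            state = action
    return BehaviorDataset(trials, rat_id=rat_id, schedule=schedule.stage_probs())
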