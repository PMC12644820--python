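"""Core Q-learning machinery: value table, TD update, softmax forecasts, RPE.

States and actions are the three maze arms, labelled by their reward role in
the *initial* training stage ("high", "mid", "low"); the physical arm is
stable even when its probability role changes across stages.  A trial's state
is the arm visited on the previous trial and its action the arm chosen now,
so the value table is a 3x3 (state, action) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "ARMS",
    "ARM_INDEX",
    "AgentParams",
    "arm_index",
    "init_q",
    "action_probabilities",
    "compute_rpe",
    "q_update",
]

#: Canonical arm ordering used for every 3x3 table in the package.
ARMS = ("high", "mid", "low")
ARM_INDEX = {name: i for i, name in enumerate(ARMS)}

#: Value attributed, before any learning, to switching arms.  Repeating an
#: arm is never rewarded, hence the zero diagonal.
Q_INIT_OFFDIAG = 0.7


def arm_index(arm: Union[int, str, np.integer]) -> int:
    """Return the canonical integer index of an arm given by name or index."""
    if isinstance(arm, str):
        try:
            return ARM_INDEX[arm]
        except KeyError:
            raise ValueError(f"unknown arm label {arm!r}; expected one of {ARMS}")
    i = int(arm)
    if not 0 <= i <= 2:
        raise ValueError(f"arm index out of range: {arm!r}")
    return i


@dataclass
class AgentParams:
    """Free parameters of the learning agent.

    ``phi`` (replayed-trial recency exponent) and ``psi`` (RPE recency
    weight) are only meaningful when the active replay policy uses them and
    may be left ``None`` otherwise, so that the free-parameter count matches
    the policy (3, 4 or 5).
    """

    alpha: float
    gamma: float
    epsilon: float
    phi: Optional[float] = None
    psi: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        # gamma = 1 is admitted: fits on real data sit on that boundary.
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.epsilon < 0.0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.phi is not None and self.phi < 0.0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if self.psi is not None and self.psi <= 0.0:
            raise ValueError(f"psi must be > 0, got {self.psi}")


def init_q() -> np.ndarray:
    """Fresh 3x3 value table: 0 on the diagonal, 0.7 off-diagonal.

    The off-diagonal bias reflects the rats' natural tendency to alternate
    arms rather than repeat them.
    """
    q = np.full((3, 3), Q_INIT_OFFDIAG, dtype=float)
    np.fill_diagonal(q, 0.0)
    return q


def action_probabilities(q: np.ndarray, state: Union[int, str], epsilon: float) -> np.ndarray:
    """Softmax forecast p_a = exp(eps * Q[s, a]) / sum_a exp(eps * Q[s, a]).

    Computed with max-subtraction for overflow safety; identical to the
    naive expression to floating-point accuracy.
    """
    if epsilon < 0.0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    row = np.asarray(q, dtype=float)[arm_index(state)]
    if not np.all(np.isfinite(row)):
        raise ValueError("non-finite Q entry in state row")
    z = epsilon * row
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def compute_rpe(
    q: np.ndarray,
    state: Union[int, str],
    action: Union[int, str],
    reward: float,
    next_state: Union[int, str],
    gamma: float,
) -> float:
    """Temporal-difference reward-prediction error.

    delta = r + gamma * max_a Q(s', a) - Q(s, a), with the max taken over
    all three actions (including the never-rewarded repeat).
    """
    q = np.asarray(q, dtype=float)
    s, a, ns = arm_index(state), arm_index(action), arm_index(next_state)
    return float(reward + gamma * q[ns].max() - q[s, a])


def q_update(
    q: np.ndarray,
    state: Union[int, str],
    action: Union[int, str],
    reward: float,
    next_state: Union[int, str],
    alpha: float,
    gamma: float,
) -> np.ndarray:
    """One TD update; returns a new table, the input is not modified.

    Only the (state, action) entry changes, by exactly alpha * delta where
    delta is :func:`compute_rpe` evaluated on the pre-update table.
    """
    q = np.array(q, dtype=float, copy=True)
    s, a = arm_index(state), arm_index(action)
    delta = compute_rpe(q, s, a, reward, next_state, gamma)
    q[s, a] += alpha * delta
    return q
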