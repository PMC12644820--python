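"""Deterministic 10-trial worked scenario with hand-derived replay-priority
tables for all four policies.

The scenario spans 5 of the 9 state-action pairs; the remaining 4 are
unexperienced and must receive replay probability exactly 0 under every
policy.  Expected values were derived by exact rational arithmetic with
agent parameters alpha = 0.5, gamma = 0.5 and RPE recency weight psi = 1.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from ..agent import ARM_INDEX, AgentParams

__all__ = ["make_worked_fixture"]

# (state, action, reward) in canonical arm order high=0, mid=1, low=2
_TRIALS: List[Tuple[int, int, int]] = [
    (0, 1, 1),
    (1, 0, 1),
    (0, 1, 0),
    (1, 2, 0),
    (2, 0, 1),
    (0, 1, 1),
    (1, 0, 0),
    (0, 2, 0),
    (2, 0, 1),
    (0, 1, 0),
]

_EXPERIENCED = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0)]


def _table(values: Dict[Tuple[int, int], float]) -> np.ndarray:
    t = np.zeros((3, 3))
    for pair, v in values.items():
        t[pair] = v
    return t


def make_worked_fixture() -> Dict:
    """Return the worked scenario and its hand-derived expected tables.

    Keys: ``trials`` (list of (state, action, reward)), ``params``, the
    final ``q`` table, per-trial stored RPEs ``deltas`` in chronological
    order, and ``expected`` mapping each policy name to its 3x3
    pair-probability table.
    """
    params = AgentParams(alpha=0.5, gamma=0.5, epsilon=1.0, phi=1.0, psi=1.0)

    # exact values from rational-arithmetic hand derivation; the single
    # unexperienced off-diagonal pair (2, 1) keeps its 0.7 initialisation
    q_final = np.array(
        [
            [0.0, 0.797021484375, 0.61181640625],
            [0.8458984375, 0.0, 0.525],
            [1.31640625, 0.7, 0.0],
        ]
    )
    deltas = [
        0.65,
        0.8125,
        -0.471875,
        -0.35,
        0.69453125,
        0.7640625,
        -0.520703125,
        -0.1763671875,
        0.53828125,
        -0.74814453125,
    ]
    expected = {
        "random": _table({p: 0.2 for p in _EXPERIENCED}),
        "reward": _table(
            {
                (0, 1): 0.19457855022708578,
                (0, 2): 0.1493640405774297,
                (1, 0): 0.20651098475366259,
                (1, 2): 0.1281693666630905,
                (2, 0): 0.32137705777873143,
            }
        ),
        "rpe_prioritised": _table({(1, 0): 1.0}),
        "rpe_proportional": _table(
            {
                (0, 1): 0.2668348419646832,
                (0, 2): 0.07146460899243211,
                (1, 0): 0.27010931394371074,
                (1, 2): 0.14182123955087303,
                (2, 0): 0.24976999554830093,
            }
        ),
    }
    return {
        "trials": list(_TRIALS),
        "experienced_pairs": list(_EXPERIENCED),
        "params": params,
        "q": q_final,
        "deltas": list(deltas),
        "expected": expected,
    }
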