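"""Between-session replay: memory buffer, the four sampling policies, and
batch offline Q updates from replayed trials.

Every trial the agent experiences is appended to a buffer together with the
reward-prediction error it produced.  Between sessions, a replay policy
picks state-action pairs (and then member trials, with a recency bias) to
re-update offline:

* ``random`` — uniform over experienced pairs;
* ``reward`` — proportional to the pairs' current Q values;
* ``rpe_prioritised`` — argmax of the recency-weighted mean absolute RPE;
* ``rpe_proportional`` — proportional to that same weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .agent import AgentParams, arm_index, compute_rpe, q_update

__all__ = [
    "POLICIES",
    "ReplayConfig",
    "BufferEntry",
    "ReplayBuffer",
    "trial_probabilities",
    "weighted_mean_rpe",
    "pair_probabilities",
    "replay_batch",
]

POLICIES = ("none", "random", "reward", "rpe_prioritised", "rpe_proportional")

#: replay counts used in paper-replication mode
PAPER_N_REPLAY = (1, 3, 5, 10, 15, 20, 30, 40, 50, 75, 100)


@dataclass
class ReplayConfig:
    policy: str = "none"
    n_replay: int = 0
    paper_mode: bool = False

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"unknown replay policy {self.policy!r}; expected {POLICIES}")
        if self.n_replay < 0:
            raise ValueError("n_replay must be non-negative")
        if self.paper_mode and self.n_replay not in (0,) + PAPER_N_REPLAY:
            raise ValueError(
                f"paper-replication mode requires n_replay in {PAPER_N_REPLAY}"
            )

    @property
    def n_free_params(self) -> int:
        """Free parameters of the corresponding fitted model (3, 4 or 5)."""
        return {
            "none": 3,
            "random": 4,
            "reward": 4,
            "rpe_prioritised": 5,
            "rpe_proportional": 5,
        }[self.policy]


@dataclass
class BufferEntry:
    state: int
    action: int
    reward: int
    delta: float  # most recently stored RPE for this trial


@dataclass
class ReplayBuffer:
    """Chronological store of experienced trials with per-pair indexing.

    Within each (state, action) pair, members keep chronological rank
    i = 1..I with 1 the oldest; recency weights use this rank.
    """

    entries: List[BufferEntry] = field(default_factory=list)
    _pair_members: Dict[Tuple[int, int], List[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, state, action, reward: int, delta: float) -> None:
        if not np.isfinite(delta):
            raise ValueError("stored RPE must be finite")
        s, a = arm_index(state), arm_index(action)
        self.entries.append(BufferEntry(s, a, int(reward), float(delta)))
        self._pair_members.setdefault((s, a), []).append(len(self.entries) - 1)

    def experienced_pairs(self) -> List[Tuple[int, int]]:
        return sorted(self._pair_members)

    def members(self, pair: Tuple[int, int]) -> List[int]:
        """Chronological buffer indices of the pair's member trials."""
        try:
            return list(self._pair_members[pair])
        except KeyError:
            raise KeyError(f"state-action pair {pair} has not been experienced")


def trial_probabilities(I: int, phi: float) -> np.ndarray:
    """P(i) = i^phi / sum_j j^phi over chronological ranks i = 1..I.

    With phi > 0 more recent (higher-rank) trials are more likely.
    """
    if I < 1:
        raise ValueError("need at least one member trial")
    ranks = np.arange(1, I + 1, dtype=float)
    w = ranks**phi
    return w / w.sum()


def weighted_mean_rpe(buffer: ReplayBuffer, pair: Tuple[int, int], psi: float) -> float:
    """Recency-weighted mean absolute RPE for one experienced pair.

    Delta_i = |delta_i| * psi^i over chronological ranks i = 1..I, averaged
    over the I member trials.
    """
    members = buffer.members(pair)
    total = 0.0
    for rank, idx in enumerate(members, start=1):
        total += abs(buffer.entries[idx].delta) * psi**rank
    return total / len(members)


def pair_probabilities(
    buffer: ReplayBuffer,
    q: np.ndarray,
    config: ReplayConfig,
    params: AgentParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Replay probability for each of the 9 state-action pairs (3x3 array).

    Pairs never experienced get exactly 0.  For the prioritised policy the
    distribution is an indicator on the argmax of the weighted mean RPE
    (exact ties broken by seeded uniform choice when an ``rng`` is given,
    by first-in-canonical-order otherwise).
    """
    if len(buffer) == 0:
        raise ValueError("replay buffer is empty")
    pairs = buffer.experienced_pairs()
    probs = np.zeros((3, 3), dtype=float)

    if config.policy == "random":
        for p in pairs:
            probs[p] = 1.0 / len(pairs)
    elif config.policy == "reward":
        qvals = np.array([max(float(np.asarray(q)[p]), 0.0) for p in pairs])
        total = qvals.sum()
        if total <= 0.0:
            # no positive value mass yet: fall back to uniform over experienced
            for p in pairs:
                probs[p] = 1.0 / len(pairs)
        else:
            for p, v in zip(pairs, qvals):
                probs[p] = v / total
    elif config.policy in ("rpe_prioritised", "rpe_proportional"):
        if params.psi is None:
            raise ValueError(f"policy {config.policy!r} requires psi")
        bars = np.array([weighted_mean_rpe(buffer, p, params.psi) for p in pairs])
        if config.policy == "rpe_prioritised":
            best = np.flatnonzero(bars == bars.max())
            pick = best[0] if rng is None or len(best) == 1 else rng.choice(best)
            probs[pairs[int(pick)]] = 1.0
        else:
            total = bars.sum()
            if total <= 0.0:
                for p in pairs:
                    probs[p] = 1.0 / len(pairs)
            else:
                for p, v in zip(pairs, bars):
                    probs[p] = v / total
    elif config.policy == "none":
        raise ValueError("policy 'none' does not sample replay pairs")
    return probs


def replay_batch(
    q: np.ndarray,
    buffer: ReplayBuffer,
    config: ReplayConfig,
    params: AgentParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run ``config.n_replay`` sequential replay events, returning the new Q.

    Each event: sample a pair from :func:`pair_probabilities` (recomputed
    per event, since stored RPEs change), sample a member trial with the
    recency bias of :func:`trial_probabilities`, apply the usual TD update
    with the trial's (s, a, r) and next state = a, then overwrite that
    trial's stored RPE with the value implied by the post-update table.

    The buffer is updated in place; the input Q is not modified.
    """
    if config.policy == "none" or config.n_replay == 0:
        return np.array(q, dtype=float, copy=True)
    if len(buffer) == 0:
        raise ValueError("cannot replay from an empty buffer")
    if params.phi is None:
        raise ValueError("replay requires the recency parameter phi")

    q = np.array(q, dtype=float, copy=True)
    for _ in range(config.n_replay):
        probs = pair_probabilities(buffer, q, config, params, rng)
        flat = probs.ravel()
        pick = rng.choice(9, p=flat)
        pair = (pick // 3, pick % 3)
        members = buffer.members(pair)
        p_rank = trial_probabilities(len(members), params.phi)
        idx = members[rng.choice(len(members), p=p_rank)]
        entry = buffer.entries[idx]
        next_state = entry.action
        q = q_update(
            q, entry.state, entry.action, entry.reward, next_state, params.alpha, params.gamma
        )
        entry.delta = compute_rpe(
            q, entry.state, entry.action, entry.reward, next_state, params.gamma
        )
    return q
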