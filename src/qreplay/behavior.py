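"""Behavioral trial logs: data model, CSV I/O, descriptive analyses, shuffling.

A trial log is one rat's chronological record of maze trials.  Each trial
carries the previously visited arm (state), the arm chosen (action), the
binary reward, a legitimacy flag (an entry is legitimate only when it
differs from the previous arm) and the training stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .agent import ARMS, arm_index

__all__ = [
    "STAGES",
    "STAGE_PROBS",
    "EPHYS_STAGE_PROBS",
    "TrialRecord",
    "BehaviorDataset",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "code_optimal",
    "arm_frequencies",
    "performance_tests",
    "shuffle_trials",
]

STAGES = ("initial", "revaluation", "reversal")
_STAGE_ORDER = {name: i for i, name in enumerate(STAGES)}

#: Reward probability of each arm per training stage (behavioural cohort).
#: Arm labels refer to the initial-stage role; the reversal stage swaps the
#: probabilities of the high and low arms, not the labels.
STAGE_PROBS: Mapping[str, Mapping[str, float]] = {
    "initial": {"high": 0.75, "mid": 0.50, "low": 0.25},
    "revaluation": {"high": 0.875, "mid": 0.50, "low": 0.125},
    "reversal": {"high": 0.125, "mid": 0.50, "low": 0.875},
}

#: Schedule of the recorded (ephys) cohort: a single pre-reversal stage.
EPHYS_STAGE_PROBS: Mapping[str, Mapping[str, float]] = {
    "initial": {"high": 0.875, "mid": 0.50, "low": 0.125},
    "reversal": {"high": 0.125, "mid": 0.50, "low": 0.875},
}

CSV_COLUMNS = [
    "rat_id",
    "session",
    "trial_index",
    "state",
    "action",
    "reward",
    "legitimate",
    "stage",
]


class SchemaError(ValueError):
    """A trial table is missing required columns or has unparseable values."""


class ValidationError(ValueError):
    """Trial rows violate the trial-log invariants."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class TrialRecord:
    rat_id: str
    session: int
    trial_index: int
    state: str
    action: str
    reward: int
    legitimate: bool
    stage: str

    def __post_init__(self):
        arm_index(self.state)
        arm_index(self.action)
        if self.stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")
        if int(self.reward) not in (0, 1):
            raise ValueError(f"reward must be binary, got {self.reward}")


@dataclass
class BehaviorDataset:
    """Ordered trials for a single rat plus session bookkeeping."""

    trials: List[TrialRecord]
    rat_id: str = field(default="")
    #: reward schedule used for optimal-choice coding; defaults to the
    #: behavioural cohort's three-stage schedule
    schedule: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: STAGE_PROBS)

    def __post_init__(self):
        if not self.rat_id and self.trials:
            self.rat_id = self.trials[0].rat_id
        validate_trials(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def sessions(self) -> List[int]:
        return sorted({t.session for t in self.trials})

    def session_trials(self, session: int) -> List[TrialRecord]:
        return [t for t in self.trials if t.session == session]

    def session_lengths(self) -> Dict[int, int]:
        lengths: Dict[int, int] = {}
        for t in self.trials:
            lengths[t.session] = lengths.get(t.session, 0) + 1
        return lengths

    def stage_of_session(self) -> Dict[int, str]:
        out: Dict[int, str] = {}
        for t in self.trials:
            out.setdefault(t.session, t.stage)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rat_id": t.rat_id,
                    "session": t.session,
                    "trial_index": t.trial_index,
                    "state": t.state,
                    "action": t.action,
                    "reward": t.reward,
                    "legitimate": t.legitimate,
                    "stage": t.stage,
                }
                for t in self.trials
            ],
            columns=CSV_COLUMNS,
        )


def validate_trials(trials: Sequence[TrialRecord]) -> None:
    """Raise :class:`ValidationError` if any trial-log invariant is broken."""
    bad_legit = [
        i for i, t in enumerate(trials) if t.legitimate != (t.action != t.state)
    ]
    if bad_legit:
        raise ValidationError(
            f"legitimate flag inconsistent with state/action on rows {bad_legit[:10]}",
            bad_legit,
        )
    bad_reward = [i for i, t in enumerate(trials) if not t.legitimate and t.reward]
    if bad_reward:
        raise ValidationError(
            f"illegitimate trials cannot be rewarded: rows {bad_reward[:10]}", bad_reward
        )
    idx = [t.trial_index for t in trials]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        rows = [i + 1 for i, (a, b) in enumerate(zip(idx, idx[1:])) if b <= a]
        raise ValidationError(f"trial_index not strictly increasing at rows {rows[:10]}", rows)
    stage_ord = [_STAGE_ORDER[t.stage] for t in trials]
    if any(b < a for a, b in zip(stage_ord, stage_ord[1:])):
        rows = [i + 1 for i, (a, b) in enumerate(zip(stage_ord, stage_ord[1:])) if b < a]
        raise ValidationError(f"stage must be non-decreasing; violated at rows {rows[:10]}", rows)


def read_trials(path, schedule: Optional[Mapping] = None) -> BehaviorDataset:
    """Read a CSV trial log (one rat) into a validated dataset."""
    # keep_default_na: rat ids like "null" must survive as strings
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log {path} is missing columns: {missing}")
    trials = [
        TrialRecord(
            rat_id=str(r.rat_id),
            session=int(r.session),
            trial_index=int(r.trial_index),
            state=str(r.state),
            action=str(r.action),
            reward=int(r.reward),
            legitimate=bool(r.legitimate),
            stage=str(r.stage),
        )
        for r in df.itertuples(index=False)
    ]
    kwargs = {"schedule": schedule} if schedule is not None else {}
    return BehaviorDataset(trials, **kwargs)


def write_trials(dataset: BehaviorDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def code_optimal(trial: TrialRecord, schedule: Optional[Mapping] = None) -> bool:
    """True iff the chosen arm maximises reward probability among legal arms.

    Legal arms are the two arms other than the current state (repeats are
    never rewarded).  Raises on a probability tie, which cannot occur under
    the task's schedules.
    """
    sched = schedule if schedule is not None else STAGE_PROBS
    probs = sched[trial.stage]
    candidates = [a for a in ARMS if a != trial.state]
    p0, p1 = probs[candidates[0]], probs[candidates[1]]
    if p0 == p1:
        raise ValueError(
            f"reward-probability tie between {candidates} in stage {trial.stage!r}"
        )
    best = candidates[0] if p0 > p1 else candidates[1]
    return trial.action == best


def arm_frequencies(dataset: BehaviorDataset, include_first: bool = False) -> pd.DataFrame:
    """Per-session proportion of entries to each arm.

    The first trial of the dataset is excluded by default because its state
    is a synthetic placeholder rather than an observed arm entry; its action
    is still a real entry, so ``include_first=True`` restores it.
    """
    trials = dataset.trials if include_first else dataset.trials[1:]
    rows = []
    for session in dataset.sessions:
        sess = [t for t in trials if t.session == session]
        if not sess:
            warnings.warn(f"session {session} empty after exclusions; skipped")
            continue
        n = len(sess)
        counts = {arm: sum(t.action == arm for t in sess) for arm in ARMS}
        rows.append({"session": session, "n_trials": n, **{a: counts[a] / n for a in ARMS}})
    return pd.DataFrame(rows)


def performance_tests(
    dataset: BehaviorDataset,
    chance_levels: Sequence[float] = (1.0 / 3.0, 0.5),
    schedule: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Per-session optimal-choice proportion with one-sided one-proportion
    z-tests against each chance level, Bonferroni-corrected over sessions."""
    sessions = dataset.sessions
    rows = []
    n_tests = len(sessions)
    for session in sessions:
        sess = dataset.session_trials(session)
        n = len(sess)
        row: dict = {"session": session, "n_trials": n}
        if n < 2:
            row["proportion_optimal"] = np.nan
            rows.append(row)
            continue
        k = sum(code_optimal(t, schedule) for t in sess)
        phat = k / n
        row["proportion_optimal"] = phat
        for p0 in chance_levels:
            z = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
            p_one_sided = stats.norm.sf(z)
            key = f"{p0:.3f}".rstrip("0").rstrip(".")
            row[f"z_vs_{key}"] = z
            row[f"p_vs_{key}"] = p_one_sided
            row[f"p_bonf_vs_{key}"] = min(1.0, p_one_sided * n_tests)
        rows.append(row)
    return pd.DataFrame(rows)


def shuffle_trials(dataset: BehaviorDataset, seed: int) -> BehaviorDataset:
    """Permute whole trials (state, action, reward move together) while
    preserving session lengths and each session's stage.

    Trials are reassigned session numbers and 1-based trial indices by their
    new position; the multiset of (state, action, reward) triples is
    conserved exactly.  Legitimacy is re-derived from the permuted
    state/action so records stay internally consistent.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.trials))
    permuted = [dataset.trials[i] for i in order]

    stage_of = dataset.stage_of_session()
    slots: List[Tuple[int, str]] = []  # (session, stage) per chronological slot
    for t in dataset.trials:
        slots.append((t.session, stage_of[t.session]))

    new_trials = []
    for k, (t, (session, stage)) in enumerate(zip(permuted, slots), start=1):
        legit = t.action != t.state
        new_trials.append(
            replace(
                t,
                session=session,
                trial_index=k,
                stage=stage,
                legitimate=legit,
                reward=t.reward if legit else 0,
            )
        )
    return BehaviorDataset(new_trials, rat_id=dataset.rat_id, schedule=dataset.schedule)
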