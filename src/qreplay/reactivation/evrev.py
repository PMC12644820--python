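"""Explained variance (EV/REV), per-pair contributions and reactivated-pair
classification.

Pairwise firing-rate correlations are computed within the PRE, TASK and
POST epochs (PRE/POST restricted to concatenated 200 ms windows around
ripple peaks), giving one correlation vector per epoch over a fixed pair
set.  EV is the squared partial correlation of the TASK and POST vectors
controlling for PRE; REV swaps PRE and POST as a bias control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .rates import DEFAULT_DT, DEFAULT_SIGMA, binless_rate
from .ripples import RippleEvent, detect_ripples
from .session import EphysSession

__all__ = [
    "CorrelationTriplet",
    "ReactivationResult",
    "epoch_correlations",
    "explained_variance",
    "pair_contributions",
    "classify_reactivated_pairs",
    "run_reactivation",
]

#: half-width of the window kept around each ripple peak in PRE/POST
RIPPLE_HALF_WINDOW = 0.100

SCOPES = ("CA1xvStr", "CA1xCA1", "vStrxvStr")


@dataclass
class CorrelationTriplet:
    """Per-pair correlations in each epoch plus the between-epoch r's."""

    pairs: List[Tuple[str, str]]
    corr_pre: np.ndarray
    corr_task: np.ndarray
    corr_post: np.ndarray
    r_task_post: float = field(init=False)
    r_task_pre: float = field(init=False)
    r_post_pre: float = field(init=False)

    def __post_init__(self):
        self.r_task_post = _pearson(self.corr_task, self.corr_post)
        self.r_task_pre = _pearson(self.corr_task, self.corr_pre)
        self.r_post_pre = _pearson(self.corr_post, self.corr_pre)


@dataclass
class ReactivationResult:
    ev: float
    rev: float
    pairs: List[Tuple[str, str]]
    contributions: np.ndarray
    labels: List[str]  # "reactivated" | "control" | "neither"
    triplet: CorrelationTriplet

    def to_dict(self) -> Dict:
        return {
            "ev": self.ev,
            "rev": self.rev,
            "ev_minus_rev": self.ev - self.rev,
            "n_pairs": len(self.pairs),
            "pairs": [list(p) for p in self.pairs],
            "contributions": self.contributions.tolist(),
            "labels": self.labels,
            "r_task_post": self.triplet.r_task_post,
            "r_task_pre": self.triplet.r_task_pre,
            "r_post_pre": self.triplet.r_post_pre,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("zero-variance correlation vector")
    return float((xd * yd).sum() / denom)


def _ripple_mask(times: np.ndarray, ripples: Sequence[RippleEvent]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for r in ripples:
        mask |= np.abs(times - r.peak) <= RIPPLE_HALF_WINDOW
    return mask


def _pair_index(session: EphysSession, scope: str) -> List[Tuple[int, int]]:
    if scope not in SCOPES:
        raise ValueError(f"unknown pair scope {scope!r}; expected one of {SCOPES}")
    by_region = {r: [i for i, u in enumerate(session.units) if u.region == r] for r in ("CA1", "vStr")}
    if scope == "CA1xvStr":
        return [(i, j) for i in by_region["CA1"] for j in by_region["vStr"]]
    region = "CA1" if scope == "CA1xCA1" else "vStr"
    idx = by_region[region]
    return [(idx[a], idx[b]) for a in range(len(idx)) for b in range(a + 1, len(idx))]


def _epoch_rates(
    session: EphysSession,
    epoch: Tuple[float, float],
    ripples: Optional[Sequence[RippleEvent]],
    dt: float,
    sigma: float,
) -> np.ndarray:
    t0, t1 = epoch
    rows = []
    mask = None
    for u in session.units:
        times, r = binless_rate(u.spikes, t0, t1, dt=dt, sigma=sigma)
        if ripples is not None and mask is None:
            mask = _ripple_mask(times, ripples)
            if not mask.any():
                raise ValueError("no ripple samples inside epoch")
        rows.append(r if mask is None else r[mask])
    return np.vstack(rows)


def _pairwise(rates: np.ndarray, pairs: Sequence[Tuple[int, int]]) -> np.ndarray:
    c = np.corrcoef(rates)
    return np.array([c[i, j] for i, j in pairs])


def epoch_correlations(
    session: EphysSession,
    ripples_pre: Sequence[RippleEvent],
    ripples_post: Sequence[RippleEvent],
    scope: str = "CA1xvStr",
    dt: float = DEFAULT_DT,
    sigma: float = DEFAULT_SIGMA,
) -> CorrelationTriplet:
    """Per-pair rate correlations in PRE (ripple windows), TASK (full epoch)
    and POST (ripple windows), for the requested pair scope.

    Pairs involving a unit with zero rate variance in any epoch are dropped
    (their correlation is undefined).
    """
    if not session.eligible:
        raise ValueError("session needs >= 5 CA1 and >= 5 vStr cells for EV analysis")
    if len(ripples_pre) == 0 or len(ripples_post) == 0:
        raise ValueError("need at least one ripple in both PRE and POST")
    idx_pairs = _pair_index(session, scope)

    rates = {
        "pre": _epoch_rates(session, session.epochs["pre"], ripples_pre, dt, sigma),
        "task": _epoch_rates(session, session.epochs["task"], None, dt, sigma),
        "post": _epoch_rates(session, session.epochs["post"], ripples_post, dt, sigma),
    }
    # units with zero variance anywhere poison correlations: drop their pairs
    ok = np.ones(len(session.units), dtype=bool)
    for r in rates.values():
        ok &= r.std(axis=1) > 0
    kept = [(i, j) for i, j in idx_pairs if ok[i] and ok[j]]
    if len(kept) < 3:
        raise ValueError("fewer than 3 usable pairs after zero-variance exclusion")

    names = [(session.units[i].unit_id, session.units[j].unit_id) for i, j in kept]
    return CorrelationTriplet(
        pairs=names,
        corr_pre=_pairwise(rates["pre"], kept),
        corr_task=_pairwise(rates["task"], kept),
        corr_post=_pairwise(rates["post"], kept),
    )


def explained_variance(triplet: CorrelationTriplet) -> Tuple[float, float]:
    """(EV, REV) from the triplet's between-epoch correlations.

    EV = ((r_TP - r_Tp * r_Pp) / sqrt((1 - r_Tp^2)(1 - r_Pp^2)))^2 with
    T = TASK, P = POST, p = PRE; REV exchanges PRE and POST.
    """
    ev = _partial_r(triplet.r_task_post, triplet.r_task_pre, triplet.r_post_pre) ** 2
    rev = _partial_r(triplet.r_task_pre, triplet.r_task_post, triplet.r_post_pre) ** 2
    return float(ev), float(rev)


def _partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0:
        raise ValueError("degenerate partial-correlation denominator")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)


def _ev_minus_rev(pre: np.ndarray, task: np.ndarray, post: np.ndarray) -> float:
    r_tp = _pearson(task, post)
    r_tq = _pearson(task, pre)
    r_pq = _pearson(post, pre)
    ev = _partial_r(r_tp, r_tq, r_pq) ** 2
    rev = _partial_r(r_tq, r_tp, r_pq) ** 2
    return ev - rev


def pair_contributions(triplet: CorrelationTriplet) -> np.ndarray:
    """Drop-one-pair-out contribution of each pair to the session EV-REV.

    contribution(pair) = (EV-REV) on all pairs - (EV-REV) without the pair.
    """
    n = len(triplet.pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs for drop-one-out contributions")
    total = _ev_minus_rev(triplet.corr_pre, triplet.corr_task, triplet.corr_post)
    contributions = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for k in range(n):
        keep[k] = False
        try:
            without = _ev_minus_rev(
                triplet.corr_pre[keep], triplet.corr_task[keep], triplet.corr_post[keep]
            )
        except ValueError:
            without = np.nan  # degenerate subset; flagged as undefined
        contributions[k] = total - without
        keep[k] = True
    return contributions


def classify_reactivated_pairs(
    contributions: np.ndarray,
    corr_pre: np.ndarray,
    corr_post: np.ndarray,
    decile: float = 0.10,
) -> List[str]:
    """Label each pair reactivated / control / neither.

    Candidates are the top ``decile`` of signed contributions; of these,
    only pairs whose PRE -> POST correlation increased are reactivated.
    Controls are the same-sized group with the smallest absolute
    contributions (excluding any reactivated pair).
    """
    contributions = np.asarray(contributions, dtype=float)
    n = len(contributions)
    if n < 10:
        raise ValueError("need >= 10 pairs for a meaningful decile split")
    k = max(1, int(np.floor(n * decile)))
    finite = np.isfinite(contributions)
    order = np.argsort(np.where(finite, contributions, -np.inf))
    top = set(order[-k:][finite[order[-k:]]].tolist())

    labels = ["neither"] * n
    reactivated = {i for i in top if corr_post[i] > corr_pre[i]}
    for i in reactivated:
        labels[i] = "reactivated"

    mag_order = np.argsort(np.where(finite, np.abs(contributions), np.inf))
    controls = [int(i) for i in mag_order if int(i) not in reactivated][:k]
    for i in controls:
        labels[i] = "control"
    return labels


def run_reactivation(
    session: EphysSession,
    scope: str = "CA1xvStr",
    decile: float = 0.10,
    dt: float = DEFAULT_DT,
    sigma: float = DEFAULT_SIGMA,
    ripple_kwargs: Optional[Dict] = None,
) -> ReactivationResult:
    """End-to-end reactivation analysis for one session.

    Detects ripples in the PRE and POST epochs of the session LFP, computes
    epoch correlations, EV/REV, drop-one-out contributions and labels."""
    kw = ripple_kwargs or {}
    fs = session.fs
    ripples = {}
    for name in ("pre", "post"):
        t0, t1 = session.epochs[name]
        seg = session.lfp[int(t0 * fs) : int(t1 * fs)]
        ripples[name] = detect_ripples(seg, fs, t_offset=t0, **kw)
    triplet = epoch_correlations(
        session, ripples["pre"], ripples["post"], scope=scope, dt=dt, sigma=sigma
    )
    ev, rev = explained_variance(triplet)
    contributions = pair_contributions(triplet)
    labels = classify_reactivated_pairs(
        contributions, triplet.corr_pre, triplet.corr_post, decile=decile
    )
    return ReactivationResult(
        ev=ev, rev=rev, pairs=triplet.pairs, contributions=contributions,
        labels=labels, triplet=triplet,
    )
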