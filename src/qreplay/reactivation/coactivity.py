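"""Cell-pair coactivity and peri-event group comparisons.

Coactivity of a pair is the pointwise minimum of the two units' smoothed
firing rates: it is high only when both cells fire together, and zero
whenever either is silent.  The raw trace is z-scored against the whole
recording session to remove rate bias before event-triggered averaging.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["coactivity", "window_means", "event_triggered_comparison"]


def coactivity(rate_a: np.ndarray, rate_b: np.ndarray) -> np.ndarray:
    """Z-scored pointwise-minimum coactivity of two rate traces on a common
    grid spanning the whole recording session."""
    rate_a = np.asarray(rate_a, dtype=float)
    rate_b = np.asarray(rate_b, dtype=float)
    if rate_a.shape != rate_b.shape:
        raise ValueError("rate traces must share a common grid")
    raw = np.minimum(rate_a, rate_b)
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero-variance coactivity trace")
    return (raw - raw.mean()) / sd


def window_means(
    trace: np.ndarray,
    times: np.ndarray,
    anchors: Sequence[float],
    window: Tuple[float, float],
) -> np.ndarray:
    """Mean of a trace in ``window`` relative to each anchor time."""
    if window[1] <= window[0]:
        raise ValueError("window must have positive length")
    out = np.empty(len(anchors))
    for i, t0 in enumerate(anchors):
        sel = (times >= t0 + window[0]) & (times < t0 + window[1])
        out[i] = trace[sel].mean() if sel.any() else np.nan
    return out


def event_triggered_comparison(
    pair_means: pd.DataFrame,
    n_permutations: int = 2000,
    seed: int = 0,
) -> Dict[str, float]:
    """Interaction of pair type x trial type on windowed coactivity.

    ``pair_means`` must have columns ``pair`` (identifier), ``group``
    ("reactivated" / "control"), ``trial_type`` (e.g. "high" / "medium")
    and ``value`` (the pair's mean windowed coactivity for that trial
    type).  The interaction statistic is the difference-of-differences of
    group means; its p-value comes from permuting group labels across pairs
    (a documented analogue of the nested mixed-effects ANOVA).  Post-hoc
    two-sided t-tests compare groups within each trial type.
    """
    required = {"pair", "group", "trial_type", "value"}
    if not required <= set(pair_means.columns):
        raise ValueError(f"pair_means must have columns {sorted(required)}")
    df = pair_means.dropna(subset=["value"])
    types = list(pd.unique(df["trial_type"]))  # first-appearance order
    if len(types) != 2:
        raise ValueError(f"expected exactly 2 trial types, got {types}")
    groups = sorted(df["group"].unique())
    if set(groups) != {"reactivated", "control"}:
        raise ValueError("groups must be 'reactivated' and 'control'")

    wide = df.pivot_table(index=["pair", "group"], columns="trial_type", values="value")
    wide = wide.dropna().reset_index()

    def interaction(frame: pd.DataFrame) -> float:
        eff = {}
        for g in ("reactivated", "control"):
            sub = frame[frame["group"] == g]
            eff[g] = sub[types[0]].mean() - sub[types[1]].mean()
        return eff["reactivated"] - eff["control"]

    observed = interaction(wide)
    rng = np.random.default_rng(seed)
    labels = wide["group"].to_numpy()
    count = 0
    shuffled = wide.copy()
    for _ in range(n_permutations):
        shuffled["group"] = rng.permutation(labels)
        if abs(interaction(shuffled)) >= abs(observed) - 1e-15:
            count += 1
    p_interaction = (count + 1) / (n_permutations + 1)

    out: Dict[str, float] = {
        "interaction_statistic": float(observed),
        "p_interaction": float(p_interaction),
    }
    for t in types:
        a = wide.loc[wide["group"] == "reactivated", t]
        b = wide.loc[wide["group"] == "control", t]
        tt = stats.ttest_ind(a, b)
        out[f"t_{t}"] = float(tt.statistic)
        out[f"p_{t}"] = float(tt.pvalue)
        out[f"mean_reactivated_{t}"] = float(a.mean())
        out[f"mean_control_{t}"] = float(b.mean())
    return out
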