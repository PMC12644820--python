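"""Self-contained recovery experiments used by the acceptance suite.

Each experiment builds its own synthetic inputs with explicit seeds, runs
the relevant pipeline stage end to end and returns summary numbers.  Sizes
are scaled to desk hardware (minutes, one core); scaling notes accompany
each function.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .agent import AgentParams
from .behavior import shuffle_trials
from .fitting import _sign_flip_pvalue, evaluate, fit_parameters
from .reactivation import detect_ripples, run_reactivation
from .replay import ReplayConfig
from .synthetic import (
    EphysGenConfig,
    Stage,
    TaskSchedule,
    default_schedule,
    generate_behavior,
    generate_ephys_session,
)

__all__ = [
    "benefit_schedule",
    "replay_benefit_experiment",
    "shuffle_control_experiment",
    "parameter_recovery_experiment",
    "reactivation_recovery_experiment",
    "ripple_recovery_experiment",
]

#: Generating agent for the replay-benefit and shuffle-control experiments:
#: slow online learning compensated by heavy RPE-prioritised replay.
BENEFIT_GEN_PARAMS = AgentParams(0.03, 0.9, 3.5, phi=1.0, psi=1.1)
BENEFIT_GEN_REPLAY = ReplayConfig("rpe_prioritised", 100)


def benefit_schedule() -> TaskSchedule:
    """Scaled-down staged schedule (10 + 4 + 2 sessions) with Bernoulli
    delivery, keeping the mid-training contingency switches."""
    return TaskSchedule(
        stages=[
            Stage("initial", 10, {"high": 0.75, "mid": 0.50, "low": 0.25}),
            Stage("revaluation", 4, {"high": 0.875, "mid": 0.50, "low": 0.125}),
            Stage("reversal", 2, {"high": 0.125, "mid": 0.50, "low": 0.875}),
        ],
        delivery="bernoulli",
    )


def _fit_pair(dataset, fit_config: ReplayConfig, maxfev_base=150, maxfev_replay=100,
              objective_seeds=(1, 2, 3), eval_seeds=range(1001, 1021)):
    """No-replay baseline fit plus a replay-policy fit warm-started from it."""
    base = fit_parameters(dataset, ReplayConfig(), maxfev=maxfev_base)
    x0 = [base.params.alpha, base.params.gamma, base.params.epsilon, 1.0]
    if fit_config.policy in ("rpe_prioritised", "rpe_proportional"):
        x0.append(1.1)
    fit = fit_parameters(
        dataset,
        fit_config,
        objective_seeds=objective_seeds,
        eval_seeds=eval_seeds,
        maxfev=maxfev_replay,
        x0=x0,
    )
    return base, fit


def replay_benefit_experiment(n_subjects: int = 8, seed: int = 0) -> Dict:
    """Fit RPE-prioritised (n = 5) vs no-replay on data from a high-replay
    RPE-prioritised generator; returns per-subject normalised errors and a
    one-sided sign-flip p-value for mean < 1."""
    sched = benefit_schedule()
    norms: List[float] = []
    for subj in range(n_subjects):
        ds, _ = generate_behavior(
            BENEFIT_GEN_PARAMS, sched, trials_per_session=50,
            seed=seed * 1000 + 300 + subj, replay=BENEFIT_GEN_REPLAY, rat_id=f"s{subj}",
        )
        base, fit = _fit_pair(ds, ReplayConfig("rpe_prioritised", 5))
        norms.append(fit.mean_error / base.mean_error)
    norms_arr = np.array(norms)
    return {
        "normalized_errors": norms,
        "mean_normalized_error": float(norms_arr.mean()),
        "p_less_than_1": _sign_flip_pvalue(norms_arr - 1.0),
        "n_subjects": n_subjects,
    }


def shuffle_control_experiment(
    n_subjects: int = 4,
    policies: Sequence[str] = ("random", "reward", "rpe_prioritised", "rpe_proportional"),
    seed: int = 0,
) -> Dict[str, Dict]:
    """Refit every policy on trial-order-shuffled data; no policy should
    improve on the no-replay baseline there."""
    sched = benefit_schedule()
    norms: Dict[str, List[float]] = {p: [] for p in policies}
    for subj in range(n_subjects):
        ds, _ = generate_behavior(
            BENEFIT_GEN_PARAMS, sched, trials_per_session=50,
            seed=seed * 1000 + 300 + subj, replay=BENEFIT_GEN_REPLAY, rat_id=f"s{subj}",
        )
        shuffled = shuffle_trials(ds, seed=seed * 100 + subj)
        base = fit_parameters(shuffled, ReplayConfig(), maxfev=150)
        x0 = [base.params.alpha, base.params.gamma, base.params.epsilon, 1.0]
        for policy in policies:
            xx = x0 + ([1.1] if policy.startswith("rpe") else [])
            fit = fit_parameters(
                shuffled,
                ReplayConfig(policy, 5),
                objective_seeds=[1, 2],
                eval_seeds=range(1001, 1011),
                maxfev=60,
                x0=xx,
            )
            norms[policy].append(fit.mean_error / base.mean_error)
    out = {}
    for policy, values in norms.items():
        arr = np.array(values)
        out[policy] = {
            "normalized_errors": values,
            "mean_normalized_error": float(arr.mean()),
            "p_less_than_1": _sign_flip_pvalue(arr - 1.0),
        }
    return out


def parameter_recovery_experiment(
    n_trials: int = 5000, seed: int = 42, maxfev: int = 200
) -> Dict:
    """Fit a no-replay model to ~n_trials synthetic trials generated at
    (alpha=0.05, gamma=0.8, epsilon=2.5); the fitted objective must not
    exceed the objective at the generating parameters (the no-replay
    objective is deterministic, so the Monte-Carlo s.e. is zero)."""
    per_session = 45
    n_sessions = max(1, round(n_trials / per_session))
    sched = default_schedule(
        n_initial=int(n_sessions * 15 / 22),
        n_revaluation=int(n_sessions * 5 / 22),
        n_reversal=max(1, n_sessions - int(n_sessions * 15 / 22) - int(n_sessions * 5 / 22)),
    )
    gen = AgentParams(0.05, 0.8, 2.5)
    ds, _ = generate_behavior(gen, sched, trials_per_session=per_session, seed=seed)
    fit = fit_parameters(ds, ReplayConfig(), maxfev=maxfev)
    gen_objective = evaluate(ds, gen).mean_error
    return {
        "n_trials": len(ds),
        "generating_objective": gen_objective,
        "fitted_objective": fit.optimizer["objective_at_optimum"],
        "fitted_params": fit.to_dict()["params"],
    }


def reactivation_recovery_experiment(seed: int = 0, n_null: int = 5) -> Dict:
    """EV-REV at carry-over 0 vs 0.8, plus reactivated-pair recovery."""
    null_diffs = []
    for k in range(n_null):
        sess, _ = generate_ephys_session(EphysGenConfig(carryover=0.0), seed=seed * 100 + k)
        res = run_reactivation(sess)
        null_diffs.append(res.ev - res.rev)
    null_arr = np.array(null_diffs)

    sess, truth = generate_ephys_session(EphysGenConfig(carryover=0.8), seed=seed * 100 + 50)
    res = run_reactivation(sess)
    truth_pairs = {tuple(p) for p in truth["reactivated_pairs"]}
    found = {p for p, l in zip(res.pairs, res.labels) if l == "reactivated"}
    precision = len(found & truth_pairs) / len(found) if found else 0.0

    sess_mid, _ = generate_ephys_session(EphysGenConfig(carryover=0.4), seed=seed * 100 + 60)
    res_mid = run_reactivation(sess_mid)

    return {
        "null_ev_minus_rev": null_diffs,
        "null_mean": float(null_arr.mean()),
        "null_se": float(null_arr.std(ddof=1) / np.sqrt(n_null)),
        "ev_high": res.ev,
        "rev_high": res.rev,
        "ev_minus_rev_mid": res_mid.ev - res_mid.rev,
        "precision": precision,
        "n_reactivated_found": len(found),
    }


def ripple_recovery_experiment(seed: int = 1) -> Dict:
    """Detect injected ripple bursts; report recovery rate and peak error."""
    sess, truth = generate_ephys_session(EphysGenConfig(carryover=0.8), seed=seed)
    hits, errors = 0, []
    total = 0
    for epoch in ("pre", "post"):
        t0, t1 = sess.epochs[epoch]
        seg = sess.lfp[int(t0 * sess.fs): int(t1 * sess.fs)]
        detected = detect_ripples(seg, sess.fs, t_offset=t0)
        for t in truth[f"ripple_times_{epoch}"]:
            total += 1
            if detected:
                err = min(abs(r.peak - t) for r in detected)
                if err <= 0.010:
                    hits += 1
                    errors.append(err)
    return {
        "n_injected": total,
        "n_recovered": hits,
        "recovery_rate": hits / total if total else 0.0,
        "max_peak_error": max(errors) if errors else None,
    }
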