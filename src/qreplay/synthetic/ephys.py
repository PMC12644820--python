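"""Synthetic CA1 / ventral-striatum session generator with known ground truth.

The generator emulates the statistical structure the reactivation pipeline
is meant to detect:

* inhomogeneous-Poisson spiking from constructed rate functions;
* designated "reactivated" CA1-vStr pairs share a latent co-fluctuation
  during TASK; during POST ripples the two members' per-ripple excitability
  is coupled with coefficient ``carryover`` (lambda), and never in PRE;
* a subset of striatal units ramps towards reward arrival (scaled by the
  trial's expectation class) and responds after rewarded outcomes in
  proportion to an RPE surrogate (reward minus expected probability);
* the LFP is pink noise plus injected 150 Hz Gaussian-envelope bursts at
  recorded times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from ..behavior import BehaviorDataset
from ..reactivation.session import EphysSession, Unit

__all__ = ["EphysGenConfig", "generate_ephys_session"]

EXPECTATION_OF_ARM = {"high": "high", "mid": "medium", "low": "low"}
EXPECT_SCALE = {"high": 1.0, "medium": 0.6, "low": 0.2}
EXPECT_PROB = {"high": 0.875, "medium": 0.5, "low": 0.125}


@dataclass
class EphysGenConfig:
    n_ca1: int = 8
    n_str: int = 8
    base_rate_range: Tuple[float, float] = (5.0, 15.0)
    rest_rate_factor: float = 0.3
    task_mod_strength: float = 0.9
    ripple_gain: float = 4.0
    ripple_mod_strength: float = 1.0
    carryover: float = 0.0  # lambda in [0, 1]
    n_reactivated_pairs: int = 6
    ripple_rate: float = 0.4  # Hz, in each rest epoch
    ripple_amp_mean: float = 80.0  # microvolt
    ripple_amp_sd: float = 10.0
    ripple_freq: float = 150.0
    ripple_duration: float = 0.12
    lfp_noise_sd: float = 30.0
    pre_duration: float = 180.0
    task_duration: float = 300.0
    post_duration: float = 180.0
    fs: float = 1250.0
    dt: float = 0.01
    ramp_gain: float = 1.5
    outcome_gain: float = 1.5
    n_reward_modulated: int = 4
    trial_spacing: float = 12.0

    def __post_init__(self):
        if not 0.0 <= self.carryover <= 1.0:
            raise ValueError("carryover must be in [0, 1]")
        if self.n_reactivated_pairs > min(self.n_ca1, self.n_str):
            raise ValueError("cannot designate more pairs than units per region")


def _slow_noise(n: int, dt: float, rng: np.random.Generator, tau: float = 0.3) -> np.ndarray:
    """Smooth unit-variance noise with correlation time ~tau seconds."""
    x = ndimage.gaussian_filter1d(rng.standard_normal(n), tau / dt)
    sd = x.std()
    return x / sd if sd > 0 else x


def _poisson_spikes(rate: np.ndarray, t0: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(np.clip(rate, 0.0, None) * dt)
    times = []
    for i in np.flatnonzero(counts):
        times.extend(t0 + (i + rng.random(counts[i])) * dt)
    return np.sort(np.asarray(times))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def _make_events(
    config: EphysGenConfig,
    task_span: Tuple[float, float],
    behavior: Optional[BehaviorDataset],
    rng: np.random.Generator,
) -> pd.DataFrame:
    t0, t1 = task_span
    n_trials = int((t1 - t0 - 2.0) // config.trial_spacing)
    if behavior is not None:
        source = behavior.trials[:n_trials]
        arms = [t.action for t in source]
        rewarded = [bool(t.reward) for t in source]
    else:
        arms = [str(a) for a in rng.choice(["high", "mid", "low"], size=n_trials, p=[0.5, 0.35, 0.15])]
        rewarded = [bool(rng.random() < EXPECT_PROB[EXPECTATION_OF_ARM[a]]) for a in arms]
    rows = []
    for k in range(min(n_trials, len(arms))):
        platform = t0 + 1.0 + k * config.trial_spacing
        rows.append(
            {
                "trial": k + 1,
                "platform_time": platform,
                "arrival_time": platform + 5.0,
                "arm": arms[k],
                "expectation": EXPECTATION_OF_ARM[arms[k]],
                "rewarded": rewarded[k],
            }
        )
    return pd.DataFrame(rows)


def _ripple_times(
    span: Tuple[float, float], rate: float, min_gap: float, rng: np.random.Generator
) -> np.ndarray:
    t0, t1 = span
    n = rng.poisson(rate * (t1 - t0 - 1.0))
    times = np.sort(rng.uniform(t0 + 0.5, t1 - 0.5, size=n))
    kept: List[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(float(t))
    return np.asarray(kept)


def generate_ephys_session(
    config: EphysGenConfig,
    behavior: Optional[BehaviorDataset] = None,
    seed: int = 0,
) -> Tuple[EphysSession, Dict]:
    """Build one synthetic session; returns (session, ground_truth).

    ``ground_truth`` lists injected ripple peak times, the designated
    reactivated pair ids, the reward-modulated unit ids and the carry-over
    coefficient actually used.
    """
    rng = np.random.default_rng(seed)
    dt = config.dt
    pre = (0.0, config.pre_duration)
    task = (pre[1], pre[1] + config.task_duration)
    post = (task[1], task[1] + config.post_duration)
    total = post[1]
    n_samples = int(round(total / dt))
    times = (np.arange(n_samples) + 0.5) * dt

    events = _make_events(config, task, behavior, rng)
    ripples = {
        "pre": _ripple_times(pre, config.ripple_rate, 0.5, rng),
        "post": _ripple_times(post, config.ripple_rate, 0.5, rng),
    }

    ca1_ids = [f"ca1_{i:02d}" for i in range(config.n_ca1)]
    str_ids = [f"str_{i:02d}" for i in range(config.n_str)]
    designated = [
        (ca1_ids[k], str_ids[k]) for k in range(config.n_reactivated_pairs)
    ]
    reward_modulated = str_ids[: config.n_reward_modulated]

    base = {
        uid: rng.uniform(*config.base_rate_range) for uid in ca1_ids + str_ids
    }

    in_task = (times >= task[0]) & (times < task[1])
    # latent TASK co-fluctuations: one per designated pair, one private
    # modulator for every unit
    pair_latents = [_slow_noise(n_samples, dt, rng) for _ in designated]
    private = {uid: _slow_noise(n_samples, dt, rng) for uid in ca1_ids + str_ids}

    # per-ripple excitability: shared within designated pairs in POST only
    def ripple_gains(epoch: str) -> Dict[str, np.ndarray]:
        n_r = len(ripples[epoch])
        shared = rng.standard_normal((len(designated), n_r))
        gains = {}
        lam = config.carryover if epoch == "post" else 0.0
        pair_of = {}
        for k, (cid, sid) in enumerate(designated):
            pair_of[cid] = k
            pair_of[sid] = k
        for uid in ca1_ids + str_ids:
            own = rng.standard_normal(n_r)
            if uid in pair_of and lam > 0:
                x = lam * shared[pair_of[uid]] + np.sqrt(1.0 - lam**2) * own
            else:
                x = own
            gains[uid] = x
        return gains

    gains = {"pre": ripple_gains("pre"), "post": ripple_gains("post")}

    # reward-approach modulation templates, shared across modulated units
    ramp = np.zeros(n_samples)
    outcome = np.zeros(n_samples)
    for ev in events.itertuples(index=False):
        scale = EXPECT_SCALE[ev.expectation]
        sel = (times >= ev.arrival_time - 2.0) & (times < ev.arrival_time)
        ramp[sel] += scale * (times[sel] - (ev.arrival_time - 2.0)) / 2.0
        if ev.rewarded:
            rpe = 1.0 - EXPECT_PROB[ev.expectation]
            sel2 = (times >= ev.arrival_time) & (times < ev.arrival_time + 1.0)
            outcome[sel2] += rpe

    units: List[Unit] = []
    for uid in ca1_ids + str_ids:
        rate = np.full(n_samples, base[uid] * config.rest_rate_factor)
        # TASK epoch: base rate with latent modulation
        mod = private[uid].copy()
        for k, (cid, sid) in enumerate(designated):
            if uid in (cid, sid):
                mod = pair_latents[k]
                break
        task_rate = base[uid] * np.clip(1.0 + config.task_mod_strength * mod, 0.05, None)
        rate[in_task] = task_rate[in_task]
        if uid in reward_modulated:
            rate[in_task] *= 1.0 + config.ramp_gain * ramp[in_task]
            rate[in_task] *= 1.0 + config.outcome_gain * outcome[in_task]
        # rest epochs: ripple-locked excitation with per-ripple gains
        for epoch in ("pre", "post"):
            for r_idx, peak in enumerate(ripples[epoch]):
                sel = np.abs(times - peak) <= 0.1
                g = 1.0 + config.ripple_mod_strength * gains[epoch][uid][r_idx]
                rate[sel] = base[uid] * config.ripple_gain * max(g, 0.05)
        region = "CA1" if uid.startswith("ca1") else "vStr"
        units.append(Unit(uid, region, _poisson_spikes(rate, 0.0, dt, rng)))

    # LFP: pink noise plus injected ripple bursts
    n_lfp = int(round(total * config.fs))
    t_lfp = np.arange(n_lfp) / config.fs
    lfp = _pink_noise(n_lfp, rng) * config.lfp_noise_sd
    env_sd = config.ripple_duration / 6.0
    for epoch in ("pre", "post"):
        for peak in ripples[epoch]:
            amp = max(rng.normal(config.ripple_amp_mean, config.ripple_amp_sd), 40.0)
            sel = np.abs(t_lfp - peak) <= config.ripple_duration
            tt = t_lfp[sel] - peak
            lfp[sel] += amp * np.exp(-0.5 * (tt / env_sd) ** 2) * np.cos(
                2 * np.pi * config.ripple_freq * tt
            )

    session = EphysSession(
        units=units,
        lfp=lfp,
        fs=config.fs,
        epochs={"pre": pre, "task": task, "post": post},
        events=events,
    )
    truth = {
        "ripple_times": np.concatenate([ripples["pre"], ripples["post"]]),
        "ripple_times_pre": ripples["pre"],
        "ripple_times_post": ripples["post"],
        "reactivated_pairs": designated,
        "reward_modulated_units": reward_modulated,
        "carryover": config.carryover,
        "base_rates": base,
        "seed": seed,
    }
    return session, truth
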