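"""Binless firing-rate estimation.

Spike trains are smoothed with a Gaussian kernel whose standard deviation
matches the variance of a 50 ms boxcar (sigma = 50 / sqrt(12) ~ 14.4 ms),
evaluated on a regular grid (10 ms by default).  The integral of the rate
over the session approximates the spike count.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["DEFAULT_DT", "DEFAULT_SIGMA", "binless_rate", "rate_matrix"]

DEFAULT_DT = 0.010
#: sigma of the Gaussian kernel matching a 50 ms boxcar's variance
DEFAULT_SIGMA = 0.050 / np.sqrt(12.0)


def binless_rate(
    spikes: np.ndarray,
    t_start: float,
    t_end: float,
    dt: float = DEFAULT_DT,
    sigma: float = DEFAULT_SIGMA,
) -> Tuple[np.ndarray, np.ndarray]:
    """Smoothed rate (Hz) of one spike train on a regular grid.

    Returns ``(times, rate)`` where ``times`` are bin centres covering
    [t_start, t_end).
    """
    spikes = np.asarray(spikes, dtype=float)
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    n = int(np.floor((t_end - t_start) / dt))
    if n < 1:
        raise ValueError("empty time range")
    edges = t_start + dt * np.arange(n + 1)
    counts, _ = np.histogram(spikes, bins=edges)
    smoothed = ndimage.gaussian_filter1d(counts.astype(float), sigma / dt, mode="constant")
    times = edges[:-1] + dt / 2.0
    return times, smoothed / dt


def rate_matrix(
    spike_trains: Sequence[np.ndarray],
    t_start: float,
    t_end: float,
    dt: float = DEFAULT_DT,
    sigma: float = DEFAULT_SIGMA,
    sample_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stacked rates, one row per unit, optionally restricted to a mask
    (e.g. concatenated ripple windows)."""
    rows = []
    for spikes in spike_trains:
        _, r = binless_rate(spikes, t_start, t_end, dt=dt, sigma=sigma)
        rows.append(r if sample_mask is None else r[sample_mask])
    return np.vstack(rows)
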