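"""Sharp-wave ripple detection from a hippocampal LFP trace.

The trace is band-passed at 120-250 Hz and the analytic-signal envelope is
z-scored over the analysed stretch.  Candidate events are excursions above
a detection threshold (3.5 SD, capped at 25 SD at the peak), with start and
end taken at the crossings of a secondary 1 SD threshold.  Events closer
than 30 ms are merged; survivors must last 10-500 ms with a peak envelope
amplitude of 30-1000 microvolt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["RippleEvent", "detect_ripples", "ripples_to_frame"]

RIPPLE_BAND = (120.0, 250.0)


@dataclass(frozen=True)
class RippleEvent:
    start: float
    peak: float
    end: float
    amplitude: float  # peak envelope amplitude, microvolt

    @property
    def duration(self) -> float:
        return self.end - self.start


def _bandpass(lfp: np.ndarray, fs: float, band: Tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, lfp)


def detect_ripples(
    lfp: np.ndarray,
    fs: float,
    band: Tuple[float, float] = RIPPLE_BAND,
    detect_sd: float = 3.5,
    max_sd: float = 25.0,
    edge_sd: float = 1.0,
    min_duration: float = 0.010,
    max_duration: float = 0.500,
    min_amplitude: float = 30.0,
    max_amplitude: float = 1000.0,
    min_separation: float = 0.030,
    t_offset: float = 0.0,
) -> List[RippleEvent]:
    """Detect ripples in an LFP trace sampled at ``fs`` Hz (microvolt units).

    ``t_offset`` shifts reported times, e.g. when the trace is an epoch cut
    out of a longer recording.  Envelope statistics are computed on the
    trace passed in, so pass the epoch to be analysed.
    """
    lfp = np.asarray(lfp, dtype=float)
    if fs < 1000.0:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band[1]} Hz band")
    filtered = _bandpass(lfp, fs, band)
    envelope = np.abs(signal.hilbert(filtered))
    mu, sd = envelope.mean(), envelope.std()
    if sd == 0:
        return []
    z = (envelope - mu) / sd

    above_edge = z > edge_sd
    # contiguous runs above the edge threshold
    edges = np.diff(above_edge.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above_edge[0]:
        starts = np.r_[0, starts]
    if above_edge[-1]:
        ends = np.r_[ends, len(z)]

    candidates = []
    for s, e in zip(starts, ends):
        if z[s:e].max() >= detect_sd:
            candidates.append([s, e])

    # merge events separated by less than min_separation
    merged: List[List[int]] = []
    gap = int(round(min_separation * fs))
    for c in candidates:
        if merged and c[0] - merged[-1][1] < gap:
            merged[-1][1] = c[1]
        else:
            merged.append(c)

    events = []
    for s, e in merged:
        seg = envelope[s:e]
        peak_idx = s + int(np.argmax(seg))
        duration = (e - s) / fs
        amplitude = float(envelope[peak_idx])
        if not min_duration <= duration <= max_duration:
            continue
        if not min_amplitude <= amplitude <= max_amplitude:
            continue
        if z[peak_idx] > max_sd:
            continue
        events.append(
            RippleEvent(
                start=t_offset + s / fs,
                peak=t_offset + peak_idx / fs,
                end=t_offset + e / fs,
                amplitude=amplitude,
            )
        )
    return events


def ripples_to_frame(events: List[RippleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start": r.start, "peak": r.peak, "end": r.end, "amplitude": r.amplitude} for r in events],
        columns=["start", "peak", "end", "amplitude"],
    )
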