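"""Container and HDF5 I/O for a simultaneous CA1 / ventral-striatum session.

Layout of the HDF5 file::

    /units/<id>/spike_times      (float64, seconds)   attrs: region
    /lfp/data                    (float64, microvolt) attrs on /lfp: fs
    /epochs                      attrs: pre, task, post -> [start, end]
    /events                      columns as datasets (one row per trial)

A plain-text events CSV (same columns) is accepted as an alternative to the
embedded events table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

__all__ = ["Unit", "EphysSession", "read_session_h5", "write_session_h5"]

REGIONS = ("CA1", "vStr")
EVENT_COLUMNS = ["trial", "platform_time", "arrival_time", "arm", "expectation", "rewarded"]

#: Minimum simultaneously recorded cells per region for EV analysis.
MIN_CELLS_PER_REGION = 5


@dataclass
class Unit:
    unit_id: str
    region: str
    spikes: np.ndarray

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        self.spikes = np.asarray(self.spikes, dtype=float)
        if np.any(np.diff(self.spikes) < 0):
            raise ValueError(f"spike times of unit {self.unit_id} are not sorted")


@dataclass
class EphysSession:
    units: List[Unit]
    lfp: np.ndarray
    fs: float
    epochs: Dict[str, Tuple[float, float]]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp, dtype=float)
        required = ("pre", "task", "post")
        missing = [k for k in required if k not in self.epochs]
        if missing:
            raise ValueError(f"missing epochs: {missing}")
        spans = [self.epochs[k] for k in required]
        for (a0, a1) in spans:
            if not a0 < a1:
                raise ValueError("epoch start must precede epoch end")
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("epochs must be disjoint and ordered pre < task < post")

    def units_in(self, region: str) -> List[Unit]:
        return [u for u in self.units if u.region == region]

    def n_cells(self, region: str) -> int:
        return len(self.units_in(region))

    @property
    def eligible(self) -> bool:
        """Session enters EV analysis only with >= 5 cells in each region."""
        return all(self.n_cells(r) >= MIN_CELLS_PER_REGION for r in REGIONS)

    @property
    def duration(self) -> float:
        return len(self.lfp) / self.fs


def write_session_h5(session: EphysSession, path) -> None:
    with h5py.File(path, "w") as f:
        units = f.create_group("units")
        for u in session.units:
            g = units.create_group(u.unit_id)
            g.create_dataset("spike_times", data=u.spikes)
            g.attrs["region"] = u.region
        lfp = f.create_group("lfp")
        lfp.create_dataset("data", data=session.lfp)
        lfp.attrs["fs"] = session.fs
        ep = f.create_group("epochs")
        for name, (start, end) in session.epochs.items():
            ep.attrs[name] = (start, end)
        ev = f.create_group("events")
        for col in session.events.columns:
            data = session.events[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            ev.create_dataset(col, data=data)


def read_session_h5(path, events_csv: Optional[str] = None) -> EphysSession:
    with h5py.File(path, "r") as f:
        units = [
            Unit(
                unit_id=str(uid),
                region=f["units"][uid].attrs["region"],
                spikes=f["units"][uid]["spike_times"][()],
            )
            for uid in sorted(f["units"], key=lambda u: (len(u), u))
        ]
        lfp = f["lfp"]["data"][()]
        fs = float(f["lfp"].attrs["fs"])
        epochs = {name: tuple(map(float, f["epochs"].attrs[name])) for name in f["epochs"].attrs}
        if events_csv is not None:
            events = pd.read_csv(events_csv)
        else:
            cols = {}
            for col in f["events"]:
                data = f["events"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            events = pd.DataFrame(cols)
    return EphysSession(units=units, lfp=lfp, fs=fs, epochs=epochs, events=events)
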