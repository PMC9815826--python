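"""HDF5 / CSV / JSON persistence for sessions, spikes, series and summaries.

Sessions go to HDF5 (``/voltage`` with an ``fs`` attribute, ``/lvp`` with
``fs``; ``animal_id`` and ``group`` as root attributes), ground truth to a
sidecar JSON, and tabular artifacts to CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import (
    GroundTruth,
    MultichannelVoltage,
    PressureSeries,
    RecordingSession,
    SpikeTrain,
)

__all__ = [
    "write_session",
    "read_session",
    "write_ground_truth",
    "read_ground_truth",
    "write_spikes_csv",
    "read_spikes_csv",
]


def write_session(path: str | Path, session: RecordingSession) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["animal_id"] = session.animal_id
        f.attrs["group"] = session.group
        g = f.create_dataset("lvp", data=session.lvp.samples)
        g.attrs["fs"] = session.lvp.fs
        g.attrs["t0"] = session.lvp.t0
        if session.voltage is not None:
            v = f.create_dataset("voltage", data=session.voltage.traces)
            v.attrs["fs"] = session.voltage.fs
            f.create_dataset("channel_mask", data=session.voltage.channel_mask)


def read_session(path: str | Path) -> RecordingSession:
    with h5py.File(path, "r") as f:
        lvp = PressureSeries(
            samples=f["lvp"][:], fs=float(f["lvp"].attrs["fs"]), t0=float(f["lvp"].attrs["t0"])
        )
        voltage = None
        if "voltage" in f:
            voltage = MultichannelVoltage(
                traces=f["voltage"][:],
                fs=float(f["voltage"].attrs["fs"]),
                channel_mask=f["channel_mask"][:].astype(bool),
            )
        return RecordingSession(
            lvp=lvp,
            animal_id=str(f.attrs["animal_id"]),
            group=str(f.attrs["group"]),
            voltage=voltage,
        )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "true_spikes": [t.tolist() for t in truth.true_spikes],
        "true_event_intervals": [list(iv) for iv in truth.true_event_intervals],
        "event_channels": [m.tolist() for m in truth.event_channels],
        "kappa": truth.kappa.tolist(),
        "regime": truth.regime,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_spikes=[np.asarray(t, dtype=float) for t in payload["true_spikes"]],
        true_event_intervals=[tuple(iv) for iv in payload["true_event_intervals"]],
        event_channels=[np.asarray(m, dtype=int) for m in payload["event_channels"]],
        kappa=np.asarray(payload["kappa"], dtype=float),
        regime=payload["regime"],
    )


def write_spikes_csv(path: str | Path, trains: list[SpikeTrain], polarity=None) -> None:
    rows = []
    for k, tr in enumerate(trains):
        pol = polarity[k] if polarity is not None else np.zeros(tr.n_spikes, dtype=int)
        for t, p in zip(tr.times, pol):
            rows.append((tr.channel_id, t, int(p)))
    pd.DataFrame(rows, columns=["channel", "time_s", "polarity"]).to_csv(path, index=False)


def read_spikes_csv(path: str | Path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for ch, sub in df.groupby("channel"):
        trains.append(
            SpikeTrain(times=np.sort(sub["time_s"].to_numpy()), channel_id=int(ch), duration=duration)
        )
    return trains
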