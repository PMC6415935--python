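"""Serialization of pipeline artifacts.

Events and behavior tables are tab-separated text; sensor epochs and RDM
series live in HDF5 containers with named axes and (for epochs) the events
table embedded as a TSV payload, so one file round-trips the full object.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import RDMSeries, SensorEpochs


def save_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_epochs(epochs: SensorEpochs, path: str | Path) -> None:
    """Write a :class:`SensorEpochs` container to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=epochs.values)
        f.create_dataset("time", data=epochs.time)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["band"] = epochs.band
        f.attrs["axes"] = json.dumps(["subject", "trial", "sensor", "time"])
        buf = _io.StringIO()
        epochs.events.to_csv(buf, sep="\t", index=False)
        f.create_dataset("events_tsv", data=buf.getvalue())


def load_epochs(path: str | Path) -> SensorEpochs:
    """Read a :class:`SensorEpochs` container; errors name the missing field."""
    with h5py.File(path, "r") as f:
        for key in ("values", "time", "events_tsv"):
            if key not in f:
                raise ValueError(f"epochs container is missing the '{key}' dataset")
        for attr in ("sfreq", "band"):
            if attr not in f.attrs:
                raise ValueError(f"epochs container is missing the '{attr}' attribute")
        values = f["values"][()]
        time = f["time"][()]
        sfreq = float(f.attrs["sfreq"])
        band = str(f.attrs["band"])
        events = pd.read_csv(_io.StringIO(f["events_tsv"][()].decode()), sep="\t")
    return SensorEpochs(values=values, time=time, sfreq=sfreq, events=events, band=band)


def save_rdm_series(series: RDMSeries, path: str | Path) -> None:
    """Write an RDM series as a 3-D array with a JSON label sidecar inside
    the same HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=series.values)
        f.create_dataset("time", data=series.time)
        f.attrs["sidecar"] = json.dumps(
            {"metric": series.metric, "image_ids": series.image_ids.tolist()}
        )


def load_rdm_series(path: str | Path) -> RDMSeries:
    with h5py.File(path, "r") as f:
        sidecar = json.loads(f.attrs["sidecar"])
        return RDMSeries(
            time=f["time"][()],
            values=f["values"][()],
            metric=sidecar["metric"],
            image_ids=np.asarray(sidecar["image_ids"]),
        )


def save_timecourse_table(
    curves: dict[str, np.ndarray], time: np.ndarray, path: str | Path
) -> None:
    """Tidy (name, time, value) table for a set of named time courses."""
    rows = []
    for name, vals in curves.items():
        vals = np.asarray(vals)
        if vals.ndim == 1:
            for t, v in zip(time, vals):
                rows.append({"name": name, "subject": -1, "time": t, "value": v})
        else:
            for s in range(vals.shape[0]):
                for t, v in zip(time, vals[s]):
                    rows.append({"name": name, "subject": s, "time": t, "value": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
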