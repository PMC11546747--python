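"""Readers and writers for the pipeline's file formats.

CSV dialect: comma-separated, UTF-8, header row, ``.`` decimal separator,
times in seconds with 6 decimals.  Traces and tensors go to HDF5; metrics,
manifests and ground-truth sidecars to JSON; configs to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import TrialEvents
from .photometry import PhotometryRecording
from .spikes import SpikeSession


def write_spikes_csv(session: SpikeSession, path) -> None:
    rows = [
        {"unit_id": uid, "spike_time_s": f"{t:.6f}"}
        for uid, st in session.units
        for t in st
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(path, index=False)
    meta = {
        "session_duration": session.session_duration,
        "group_label": session.group_label,
        "sex": session.sex,
        "unit_ids": [uid for uid, _ in session.units],
        "profiles": session.profiles,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, default=str, indent=1))


def read_spikes_csv(path) -> SpikeSession:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["unit_id", "spike_time_s"]:
        raise ValueError(f"malformed spikes CSV header in {path}: {list(df.columns)}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    duration = meta.get("session_duration", float(df["spike_time_s"].max()) if len(df) else 0.0)
    uids = meta.get("unit_ids", sorted(df["unit_id"].unique()))
    grouped = {uid: g["spike_time_s"].to_numpy(dtype=float) for uid, g in df.groupby("unit_id")}
    units = [(uid, grouped.get(uid, np.array([]))) for uid in uids]
    profiles = meta.get("profiles")
    if profiles is not None:
        profiles = {type(uids[0])(k) if not isinstance(k, type(uids[0])) else k: v
                    for k, v in profiles.items()}
    return SpikeSession(
        units=units,
        session_duration=duration,
        group_label=meta.get("group_label", "CTRL"),
        sex=meta.get("sex", "F"),
        profiles=profiles,
    )


def write_tensor_h5(X: np.ndarray, path, time: np.ndarray | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=np.asarray(X, dtype=float))
        if time is not None:
            f.create_dataset("time_s", data=np.asarray(time, dtype=float))


def read_tensor_h5(path) -> tuple[np.ndarray, np.ndarray | None]:
    import h5py

    with h5py.File(path, "r") as f:
        X = f["tensor"][:]
        time = f["time_s"][:] if "time_s" in f else None
    return X, time


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def load_session_bundle(path) -> dict:
    """Load a session directory: events.csv plus optional traces/spikes.

    Expected members of ``path``: ``events.csv`` (required),
    ``photometry.h5`` and ``spikes.csv`` (optional).  Each file is
    validated on load; absent optional members are simply omitted from the
    returned dict.
    """
    p = Path(path)
    events_path = p / "events.csv"
    if not events_path.exists():
        raise FileNotFoundError(f"missing required events file: {events_path}")
    header = events_path.read_text().splitlines()[0].strip()
    if header != "time_s,event,trial_index":
        raise ValueError(f"malformed events header at {events_path} line 1: {header!r}")
    bundle = {"events": TrialEvents.from_csv(events_path)}
    if (p / "photometry.h5").exists():
        bundle["photometry"] = PhotometryRecording.from_hdf5(p / "photometry.h5")
    if (p / "spikes.csv").exists():
        bundle["spikes"] = read_spikes_csv(p / "spikes.csv")
    return bundle
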