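"""Serialization: session directory layout, epoch sets, and BrainVision.

A session directory holds the signals as binary array files with JSON
sidecars (channel names, rate, units) and the events/trial tables as CSV:

    session/
      eeg.npy         (32, n_samples) float64, microvolts
      eeg.json        {"channels": [...], "rate": 500.0, "units": "uV"}
      kinematics.npy  (n_trials, n_samples, 3) float64, meters
      kinematics.json {"rate": 120.0, "t0": [per-trial start time, s]}
      events.csv      trial, type, time, code
      trials.csv      trial, block, hand, code, t_ready, t_task, t_go, t_onset

EEG can additionally be exported to BrainVision (.vhdr/.vmrk/.eeg,
IEEE float32 multiplexed) for interoperability with standard EEG tools,
and BrainVision recordings can be read back (via :mod:`mne`) with a
marker-to-event mapping.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .eeg_preprocess import EpochSet
from .kinematics import Trajectory
from .synthetic_session import Session
from .task_model import parse_condition_code

__all__ = [
    "save_session",
    "load_session",
    "save_epochs",
    "load_epochs",
    "write_brainvision",
    "read_brainvision",
]


def save_session(session: Session, path) -> Path:
    """Write a session to the documented directory layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if session.eeg is not None:
        np.save(path / "eeg.npy", session.eeg)
        with open(path / "eeg.json", "w") as fh:
            json.dump(
                {"channels": list(session.ch_names), "rate": session.rate, "units": "uV"},
                fh,
                indent=2,
            )
    kin = np.stack([t.position for t in session.kinematics])
    np.save(path / "kinematics.npy", kin)
    with open(path / "kinematics.json", "w") as fh:
        json.dump(
            {
                "rate": session.kinematics[0].rate,
                "t0": [float(t.time[0]) for t in session.kinematics],
                "units": "m",
            },
            fh,
            indent=2,
        )
    session.events.to_csv(path / "events.csv", index=False)
    session.trial_table.to_csv(path / "trials.csv", index=False)
    return path


def load_session(path) -> Session:
    """Read a session directory written by :func:`save_session`."""
    path = Path(path)
    eeg = None
    rate = 500.0
    ch_names: Tuple[str, ...] = ()
    if (path / "eeg.npy").exists():
        eeg = np.load(path / "eeg.npy")
        meta = json.loads((path / "eeg.json").read_text())
        rate = float(meta["rate"])
        ch_names = tuple(meta["channels"])
    kin_meta = json.loads((path / "kinematics.json").read_text())
    kin_arr = np.load(path / "kinematics.npy")
    kin_rate = float(kin_meta["rate"])
    trajectories = [
        Trajectory(
            time=t0 + np.arange(pos.shape[0]) / kin_rate,
            position=pos,
            rate=kin_rate,
        )
        for t0, pos in zip(kin_meta["t0"], kin_arr)
    ]
    events = pd.read_csv(path / "events.csv")
    trials = pd.read_csv(path / "trials.csv")
    return Session(
        eeg=eeg,
        rate=rate,
        ch_names=ch_names,
        events=events,
        kinematics=trajectories,
        trial_table=trials,
    )


def save_epochs(epochs: EpochSet, path) -> Path:
    """Write an epoch set as ``<path>.npy`` + ``<path>.json`` sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), epochs.data)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "alignment": epochs.alignment,
                "rate": epochs.rate,
                "t_start": epochs.t_start,
                "channels": list(epochs.ch_names),
                "trial_ids": [int(i) for i in epochs.trial_ids],
                "conditions": [c.code for c in epochs.conditions],
            },
            fh,
            indent=2,
        )
    return path


def load_epochs(path) -> EpochSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        alignment=meta["alignment"],
        conditions=tuple(parse_condition_code(c) for c in meta["conditions"]),
        trial_ids=np.asarray(meta["trial_ids"], dtype=int),
        rate=float(meta["rate"]),
        t_start=float(meta["t_start"]),
        ch_names=tuple(meta["channels"]),
    )


def write_brainvision(session: Session, basename) -> Path:
    """Export the continuous EEG to BrainVision (.vhdr/.vmrk/.eeg).

    Data are written as multiplexed IEEE float32 in microvolts; events
    become Stimulus markers with description ``<type>/<code>``.
    """
    if session.eeg is None:
        raise ValueError("session has no EEG record")
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    n_ch = session.eeg.shape[0]
    interval_us = 1e6 / session.rate

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(session.ch_names, start=1):
        header.append(f"Ch{i}={ch},,1,µV")
    (base.parent / f"{stem}.vhdr").write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    events = session.events.sort_values("time").reset_index(drop=True)
    for i, row in enumerate(events.itertuples(), start=2):
        pos = int(round(row.time * session.rate)) + 1  # 1-based samples
        desc = f"{row.type}/{row.code}"
        markers.append(f"Mk{i}=Stimulus,{desc},{pos},1,0")
    (base.parent / f"{stem}.vmrk").write_text("\n".join(markers) + "\n", encoding="utf-8")

    session.eeg.T.astype("<f4").tofile(base.parent / f"{stem}.eeg")
    return base.parent / f"{stem}.vhdr"


def read_brainvision(vhdr_path, marker_map: Optional[Dict[str, str]] = None):
    """Read a BrainVision recording via :mod:`mne`.

    Returns ``(data_uV, rate, ch_names, events)`` where ``events`` is a
    table with columns type/time/code parsed from Stimulus marker
    descriptions (``<type>/<code>``); ``marker_map`` optionally renames
    raw marker descriptions to event types first.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    rows = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("Stimulus/"):
            desc = desc[len("Stimulus/"):]
        if marker_map:
            desc = marker_map.get(desc, desc)
        parts = desc.split("/")
        rows.append(
            {
                "type": parts[0],
                "time": float(ann["onset"]),
                "code": parts[1] if len(parts) > 1 else "",
            }
        )
    events = pd.DataFrame(rows, columns=["type", "time", "code"])
    return data, float(raw.info["sfreq"]), list(raw.ch_names), events
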