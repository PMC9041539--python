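"""Session serialization: delimited matrix + JSON sidecar, plus EDF reading.

A session on disk is a directory with

* ``data.tsv`` — tab-separated channels x samples matrix (microvolts),
* ``sidecar.json`` — channel labels, sampling rate, events,
* ``ground_truth.json`` — optional planted-parameter record.

EDF files are read through MNE when available (reading only; recordings
generated here are written in the delimited format).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EEGRecording, Event
from .synth import GroundTruth

DATA_FILE = "data.tsv"
SIDECAR_FILE = "sidecar.json"
TRUTH_FILE = "ground_truth.json"


def save_session(
    directory: str | Path,
    rec: EEGRecording,
    ground_truth: GroundTruth | None = None,
    fmt: str = "%.6f",
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / DATA_FILE, rec.data, fmt=fmt, delimiter="\t")
    sidecar = {
        "channel_labels": list(rec.channel_labels),
        "fs": rec.fs,
        "events": [
            {"sample": int(ev.sample), "condition": ev.condition, "hand": ev.hand}
            for ev in rec.events
        ],
    }
    (directory / SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    if ground_truth is not None:
        (directory / TRUTH_FILE).write_text(
            json.dumps(ground_truth.to_json_dict(), indent=1, sort_keys=True)
        )
    return directory


def load_session(directory: str | Path) -> tuple[EEGRecording, GroundTruth | None]:
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR_FILE).read_text())
    data = np.loadtxt(directory / DATA_FILE, delimiter="\t", ndmin=2)
    events = [
        Event(sample=e["sample"], condition=e["condition"], hand=e["hand"])
        for e in sidecar["events"]
    ]
    rec = EEGRecording(
        data=data, fs=sidecar["fs"], channel_labels=sidecar["channel_labels"], events=events
    )
    truth_path = directory / TRUTH_FILE
    gt = None
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        gt = GroundTruth(
            trials=payload["trials"],
            erd_factors=payload["erd_factors"],
            edges=payload["edges"],
        )
    return rec, gt


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording; annotations of the form ``condition/hand`` become
    events. Requires MNE."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional 'mne' dependency") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if "/" in desc:
            cond, hand = desc.split("/", 1)
            events.append(Event(sample=int(round(onset * fs)), condition=cond, hand=hand))
    return EEGRecording(data=data, fs=fs, channel_labels=list(raw.ch_names), events=events)
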