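"""Reading and writing recordings and schedules.

The internal container is a plain NPZ archive that round-trips
:class:`~hftmspc.preprocess.EEGRecording` losslessly; trial schedules
serialise to JSON.  Standard EEG formats (BrainVision ``.vhdr``, EDF
``.edf``) are read through :mod:`mne` when it is installed; mne is an
optional dependency imported lazily.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .preprocess import EEGRecording
from .stimulus_model import Cycle, TrialSchedule

__all__ = [
    "save_recording",
    "load_recording",
    "read_raw_eeg",
    "schedule_to_json",
    "schedule_from_json",
]


def save_recording(path: str | Path, recording: EEGRecording) -> None:
    """Write a recording to a lossless NPZ container."""
    ev_samples = np.array([s for s, _ in recording.events], dtype=np.int64)
    ev_labels = np.array([lab for _, lab in recording.events], dtype=object)
    np.savez(
        path,
        data=recording.data,
        fs=recording.fs,
        channel_labels=np.array(recording.channel_labels, dtype=object),
        channel_positions=(
            recording.channel_positions
            if recording.channel_positions is not None
            else np.zeros((0, 3))
        ),
        event_samples=ev_samples,
        event_labels=ev_labels,
    )


def load_recording(path: str | Path) -> EEGRecording:
    with np.load(path, allow_pickle=True) as z:
        positions = z["channel_positions"]
        return EEGRecording(
            data=z["data"],
            fs=float(z["fs"]),
            channel_labels=[str(x) for x in z["channel_labels"]],
            channel_positions=positions if positions.size else None,
            events=[(int(s), str(lab)) for s, lab in zip(z["event_samples"], z["event_labels"])],
        )


def read_raw_eeg(path: str | Path) -> EEGRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording via mne.

    Voltages are converted from volts (mne's unit) to microvolts.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in {".vhdr", ".edf"}:
        raise ValueError(f"unsupported EEG format {suffix!r}; expected .vhdr or .edf")
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading standard EEG formats requires mne") from err
    reader = mne.io.read_raw_brainvision if suffix == ".vhdr" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    events = [
        (int(onset * raw.info["sfreq"]), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def schedule_to_json(schedule: TrialSchedule) -> str:
    d = dataclasses.asdict(schedule)
    d["cycles"] = [dataclasses.asdict(c) for c in schedule.cycles]
    return json.dumps(d, indent=2)


def schedule_from_json(text: str) -> TrialSchedule:
    d = json.loads(text)
    cycles = tuple(Cycle(**c) for c in d.pop("cycles"))
    d["contrast_bounds"] = tuple(d["contrast_bounds"])
    return TrialSchedule(cycles=cycles, **d)
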