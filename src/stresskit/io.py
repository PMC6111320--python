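"""Readers and writers for recording sessions.

Native format is deliberately plain text so fixtures are inspectable and
diff-able: a CSV samples file (header = channel roles, first column =
sample index), a JSON events sidecar (marker name -> seconds) and a JSON
metadata sidecar (subject id, sampling rate, self-perceived stress
answers).  Floats are written with 17 significant digits so a round trip
is bit-exact.  EDF import is read-only, with channel labels matched
case-insensitively onto the canonical roles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    CHANNEL_ROLES,
    ChannelMap,
    EventTimeline,
    FormatError,
    SubjectSession,
)

__all__ = ["read_session", "write_session", "session_paths"]


def session_paths(path: str | Path) -> dict[str, Path]:
    """The three native-format file paths derived from a base path/stem."""
    stem = Path(path)
    return {
        "samples": stem.with_suffix(".samples.csv"),
        "events": stem.with_suffix(".events.json"),
        "meta": stem.with_suffix(".meta.json"),
    }


def write_session(session: SubjectSession, path: str | Path, format: str = "native") -> None:
    """Write *session* to disk; ``read_session`` inverts it bit-exactly."""
    if format != "native":
        raise ValueError(f"unsupported write format: {format!r}")
    paths = session_paths(path)
    paths["samples"].parent.mkdir(parents=True, exist_ok=True)

    df = pd.DataFrame(session.channels.T, columns=list(session.channel_map.roles))
    df.insert(0, "index", np.arange(session.n_samples))
    # 17 significant digits: float64 -> text -> float64 is the identity
    df.to_csv(paths["samples"], index=False, float_format="%.17g")
    paths["events"].write_text(json.dumps(session.timeline.as_dict(), indent=1))
    meta = {
        "subject_id": session.subject_id,
        "sampling_rate": session.sampling_rate,
        "spsl": list(session.spsl),
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path, format: str = "native") -> SubjectSession:
    """Read a session written by :func:`write_session`, or import an EDF file."""
    if format == "native":
        return _read_native(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported read format: {format!r}")


def _read_native(path: str | Path) -> SubjectSession:
    paths = session_paths(path)
    for p in paths.values():
        if not p.exists():
            raise FormatError(f"missing session file: {p}")

    with open(paths["samples"]) as fh:
        header = fh.readline().strip().split(",")
    if len(header) != 9 or header[0] != "index":
        raise FormatError(f"bad samples header: {header}")
    roles = tuple(header[1:])
    if sorted(roles) != sorted(CHANNEL_ROLES):
        raise FormatError(f"samples header does not list the 8 roles once each: {roles}")
    try:
        data = pd.read_csv(
            paths["samples"], dtype=np.float64, float_precision="round_trip"
        ).to_numpy()
    except ValueError as exc:
        raise FormatError(f"unparseable samples file {paths['samples']}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 9:
        raise FormatError(f"samples file has wrong shape {data.shape}, expected (n, 9)")

    events = json.loads(paths["events"].read_text())
    meta = json.loads(paths["meta"].read_text())
    return SubjectSession(
        subject_id=str(meta["subject_id"]),
        sampling_rate=float(meta["sampling_rate"]),
        channels=data[:, 1:].T,
        channel_map=ChannelMap(roles),
        timeline=EventTimeline.from_dict(events),
        spsl=tuple(meta["spsl"]),
    )


#: case-insensitive substrings used to match EDF channel labels to roles
_EDF_LABEL_HINTS = {
    "EEG_Fp1": ("fp1",),
    "EEG_Fp2": ("fp2",),
    "EEG_F3": ("f3",),
    "EEG_F4": ("f4",),
    "ECG": ("ecg", "ekg"),
    "EMG_medial": ("emg_medial", "emg medial", "emg1"),
    "EMG_lateral": ("emg_lateral", "emg lateral", "emg2"),
    "GSR_voltage": ("gsr", "eda"),
}


def _read_edf(path: str | Path) -> SubjectSession:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("EDF import requires the 'mne' package") from exc

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.lower() for ch in raw.ch_names]

    indices: dict[str, int] = {}
    for role, hints in _EDF_LABEL_HINTS.items():
        matches = [
            i for i, lab in enumerate(labels) if any(h in lab for h in hints)
        ]
        # F3/F4 hints also occur inside Fp-channel labels; exclude taken ones
        matches = [i for i in matches if i not in indices.values()]
        if role in ("EEG_F3", "EEG_F4"):
            matches = [i for i in matches if "fp" not in labels[i]]
        if not matches:
            raise FormatError(f"EDF file has no channel matching role {role}")
        if len(matches) > 1:
            raise FormatError(
                f"EDF role {role} is ambiguous: channels {[raw.ch_names[i] for i in matches]}"
            )
        indices[role] = matches[0]

    channels = np.vstack([raw.get_data(picks=[indices[r]])[0] for r in CHANNEL_ROLES])
    events = _edf_annotations_to_timeline(raw)
    if events is None:
        events = EventTimeline()
        if channels.shape[1] / raw.info["sfreq"] < events.rs2_end:
            raise FormatError(
                "EDF file carries no timeline annotations and is shorter than "
                "the default protocol; cannot place experimental phases"
            )
    return SubjectSession(
        subject_id=Path(path).stem,
        sampling_rate=float(raw.info["sfreq"]),
        channels=channels,
        channel_map=ChannelMap(CHANNEL_ROLES),
        timeline=events,
        spsl=(0, 0, 0),
    )


def _edf_annotations_to_timeline(raw) -> EventTimeline | None:
    marks = {}
    for ann in raw.annotations:
        name = str(ann["description"]).strip().lower()
        if name in EventTimeline().as_dict():
            marks[name] = float(ann["onset"])
    return EventTimeline.from_dict(marks) if marks else None
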