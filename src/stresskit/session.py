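"""Data model for multichannel stress-study recordings.

A recording session holds eight simultaneously sampled channels (four
frontal EEG electrodes, one ECG, two trapezius EMG electrodes and one
galvanic-skin-response voltage channel), an event timeline marking the
experimental phases (maximum voluntary contraction test, resting-state
blocks, stress task, relaxation), and the subject's three self-perceived
stress ratings.  All times are seconds from recording start; sample index
= round(t * fs); epochs are half-open intervals [start, start + window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "CHANNEL_ROLES",
    "ChannelMap",
    "EventTimeline",
    "SubjectSession",
    "EpochGrid",
    "build_epoch_grid",
    "regions_of_interest",
]

#: Canonical channel roles, in default channel-index order 0..7.
CHANNEL_ROLES = (
    "EEG_Fp1",
    "EEG_Fp2",
    "EEG_F3",
    "EEG_F4",
    "ECG",
    "EMG_medial",   # trapezius electrode closer to the backbone
    "EMG_lateral",  # trapezius electrode further from the backbone
    "GSR_voltage",
)

EEG_ROLES = ("EEG_Fp1", "EEG_Fp2", "EEG_F3", "EEG_F4")


class ValidationError(ValueError):
    """A session, timeline or channel map violates a structural invariant."""


class FormatError(ValueError):
    """A file on disk cannot be interpreted as a valid session."""


@dataclass(frozen=True)
class ChannelMap:
    """Mapping channel index (0..7) -> physiological role.

    Exactly four EEG roles, one ECG, two EMG and one GSR role must be
    present, each at most once.
    """

    roles: tuple[str, ...] = CHANNEL_ROLES

    def __post_init__(self) -> None:
        if len(self.roles) != 8:
            raise ValidationError(f"channel map needs 8 entries, got {len(self.roles)}")
        if sorted(self.roles) != sorted(CHANNEL_ROLES):
            raise ValidationError(
                "channel map must contain each of "
                f"{CHANNEL_ROLES} exactly once, got {self.roles}"
            )

    def index_of(self, role: str) -> int:
        return self.roles.index(role)

    @property
    def eeg_indices(self) -> tuple[int, ...]:
        return tuple(self.roles.index(r) for r in EEG_ROLES)


# Marker names in their required temporal order.
TIMELINE_MARKERS = (
    "mvc_start",
    "mvc_end",
    "rs1_start",
    "rs1_end",
    "t1",
    "mist_train_start",
    "mist_task_start",
    "mist_end",
    "t2",
    "relax_start",
    "relax_end",
    "t3",
    "rs2_start",
    "rs2_end",
)


@dataclass(frozen=True)
class EventTimeline:
    """Named event markers, in seconds from recording start.

    Markers must be non-decreasing in the canonical order.  The default
    values realise the study protocol: a 5-s maximum voluntary
    contraction, 2 min resting state (RS1), 3 min stress-task training
    plus 6 min task, 10 min relaxation, 2 min resting state (RS2), with
    30-s transition periods between parts.
    """

    mvc_start: float = 15.0
    mvc_end: float = 20.0
    rs1_start: float = 50.0
    rs1_end: float = 170.0
    t1: float = 175.0
    mist_train_start: float = 200.0
    mist_task_start: float = 380.0
    mist_end: float = 740.0
    t2: float = 745.0
    relax_start: float = 770.0
    relax_end: float = 1370.0
    t3: float = 1375.0
    rs2_start: float = 1400.0
    rs2_end: float = 1520.0

    def __post_init__(self) -> None:
        vals = [getattr(self, m) for m in TIMELINE_MARKERS]
        for (na, a), (nb, b) in zip(
            zip(TIMELINE_MARKERS, vals), zip(TIMELINE_MARKERS[1:], vals[1:])
        ):
            if b < a:
                raise ValidationError(
                    f"timeline markers out of order: {nb}={b} < {na}={a}"
                )

    def as_dict(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in TIMELINE_MARKERS}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "EventTimeline":
        unknown = set(d) - set(TIMELINE_MARKERS)
        if unknown:
            raise FormatError(f"unknown timeline markers: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def scaled(self, **overrides: float) -> "EventTimeline":
        return replace(self, **overrides)

    @property
    def span(self) -> float:
        return self.rs2_end


@dataclass
class SubjectSession:
    """One subject's 8-channel recording, timeline and stress ratings.

    ``spsl`` is the triple of self-perceived stress answers (0-4 scale)
    collected after RS1 (T1), after the stress task (T2) and after the
    relaxation session (T3).
    """

    subject_id: str
    sampling_rate: float
    channels: np.ndarray  # shape (8, n_samples)
    channel_map: ChannelMap = field(default_factory=ChannelMap)
    timeline: EventTimeline = field(default_factory=EventTimeline)
    spsl: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] != 8:
            raise ValidationError(
                f"channels must be (8, n_samples), got {self.channels.shape}"
            )
        if self.channels.shape[1] == 0:
            raise ValidationError("channels are empty")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.duration < self.timeline.rs2_end:
            raise ValidationError(
                f"recording ({self.duration:.3f} s) ends before "
                f"rs2_end ({self.timeline.rs2_end} s)"
            )
        if len(self.spsl) != 3 or any(not 0 <= int(v) <= 4 for v in self.spsl):
            raise ValidationError(f"spsl must be three integers in 0..4, got {self.spsl}")
        self.spsl = tuple(int(v) for v in self.spsl)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.channels.shape[1] / self.sampling_rate

    def channel(self, role: str) -> np.ndarray:
        """Return the samples of the channel carrying *role*."""
        return self.channels[self.channel_map.index_of(role)]

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        """Half-open sample slice for the time interval [start_s, end_s)."""
        fs = self.sampling_rate
        return slice(int(round(start_s * fs)), int(round(end_s * fs)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubjectSession):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.sampling_rate == other.sampling_rate
            and self.channel_map == other.channel_map
            and self.timeline == other.timeline
            and self.spsl == other.spsl
            and self.channels.shape == other.channels.shape
            and bool(np.array_equal(self.channels, other.channels))
        )


@dataclass(frozen=True)
class EpochGrid:
    """Contiguous non-overlapping fixed-length epochs inside a region.

    A trailing remainder shorter than one window is dropped, so
    ``len(grid) == floor((end - start) / window)``.
    """

    region_start_s: float
    region_end_s: float
    window_s: float
    starts: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return np.asarray(self.starts) + self.window_s / 2.0

    def intervals(self) -> list[tuple[float, float]]:
        return [(s, s + self.window_s) for s in self.starts]


def build_epoch_grid(region: tuple[float, float], window_s: float) -> EpochGrid:
    """Segment ``region = (start_s, end_s)`` into non-overlapping epochs."""
    start, end = float(region[0]), float(region[1])
    if not window_s > 0:
        raise ValueError(f"window_s must be > 0, got {window_s}")
    if not end > start:
        raise ValueError(f"region end must exceed start, got {region}")
    # tiny tolerance so that e.g. (0, 120.0) at window 2 yields exactly 60
    n = int(math.floor((end - start) / window_s + 1e-9))
    starts = tuple(start + i * window_s for i in range(n))
    return EpochGrid(start, end, float(window_s), starts)


def regions_of_interest(timeline: EventTimeline) -> dict[str, tuple[float, float]]:
    """The analysis regions: central minute of each resting-state block,
    the full stress session (training + task) and the full relaxation
    session.  On the default timeline these hold 30 + 270 + 300 + 30 = 630
    two-second epochs."""
    t = timeline
    return {
        "rs1": (t.rs1_start + 30.0, t.rs1_start + 90.0),
        "mist": (t.mist_train_start, t.mist_end),
        "relax": (t.relax_start, t.relax_end),
        "rs2": (t.rs2_start + 30.0, t.rs2_start + 90.0),
    }
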