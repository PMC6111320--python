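"""Zero-phase Butterworth filtering, epoch extraction and normalization.

Each biosignal gets its own band-pass preset: EEG 1-48 Hz (order 4),
ECG 16-24 Hz (order 2, to enhance the R-peak of the QRS complex) and
EMG 1-350 Hz (order 2).  Filters are applied forward-backward
(``sosfiltfilt``), so the output has zero phase lag and the effective
magnitude response is the squared design response.  Filtering is done on
the full continuous channel *before* segmentation, so epoch interiors
are free of filter warm-up transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session import EpochGrid, SubjectSession, build_epoch_grid, regions_of_interest

__all__ = [
    "FilterSpec",
    "FILTER_PRESETS",
    "design_bandpass",
    "filter_zero_phase",
    "detrend_normalize",
    "Epoch",
    "extract_region_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth band-pass design, applied forward-backward."""

    low_hz: float
    high_hz: float
    order: int
    fs: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= self.fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz is at or above Nyquist ({self.fs / 2} Hz)"
            )
        if self.order not in (2, 4):
            raise ValueError(f"order must be 2 or 4, got {self.order}")

    @property
    def sos(self) -> np.ndarray:
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=self.fs, output="sos"
        )

    def magnitude(self, freqs_hz) -> np.ndarray:
        """Effective magnitude response after forward-backward application."""
        _, h = sps.sosfreqz(self.sos, worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return np.abs(h) ** 2


#: (low_hz, high_hz, order) per modality
_PRESET_PARAMS = {"eeg": (1.0, 48.0, 4), "ecg": (16.0, 24.0, 2), "emg": (1.0, 350.0, 2)}


def design_bandpass(low_hz: float, high_hz: float, order: int, fs: float) -> FilterSpec:
    """Design a stable Butterworth band-pass; raises on band edges >= Nyquist."""
    return FilterSpec(low_hz, high_hz, order, fs)


def get_preset(name: str, fs: float) -> FilterSpec:
    try:
        low, high, order = _PRESET_PARAMS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown filter preset {name!r}; known: {sorted(_PRESET_PARAMS)}")
    return design_bandpass(low, high, order, fs)


FILTER_PRESETS = _PRESET_PARAMS


def _min_length(spec: FilterSpec) -> int:
    # warm-up of the slowest pole; sosfiltfilt also needs > its padlen
    return int(3 * spec.order * spec.fs / spec.low_hz)


def filter_zero_phase(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-backward (zero-phase) band-pass filtering.

    Output has the same length as the input and zero group delay.
    """
    x = np.asarray(x, dtype=np.float64)
    sos = spec.sos
    min_n = 3 * (2 * sos.shape[0] + 1)
    if x.size <= min_n:
        raise ValueError(
            f"input of {x.size} samples is too short for zero-phase filtering; "
            f"need more than {min_n} samples "
            f"({_min_length(spec)} recommended for a clean warm-up)"
        )
    padlen = min(x.size - 1, _min_length(spec))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def detrend_normalize(samples: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend, then z-score to mean 0, sd 1.

    Works on the last axis; a (residually) constant epoch maps to zeros
    rather than raising, with a warning, so batch pipelines stay total.
    """
    x = np.asarray(samples, dtype=np.float64)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("epoch must hold at least 2 samples")
    # least-squares linear fit, vectorized over leading axes
    t = np.arange(n) - (n - 1) / 2.0
    mean = x.mean(axis=-1, keepdims=True)
    slope = ((x - mean) * t).sum(axis=-1, keepdims=True) / (t * t).sum()
    x = x - mean - slope * t
    sd = x.std(axis=-1, keepdims=True)
    flat = sd < 1e-12 * (1.0 + np.abs(x).max(initial=0.0))
    if np.any(flat):
        warnings.warn("constant epoch encountered; normalized to all-zeros")
    sd = np.where(flat, 1.0, sd)
    out = (x - x.mean(axis=-1, keepdims=True)) / sd
    return np.where(flat, 0.0, out)


@dataclass
class Epoch:
    """One fixed-length window of (possibly multi-channel) samples."""

    samples: np.ndarray  # (n_channels, n) or (n,)
    start_s: float
    window_s: float
    roles: tuple[str, ...]
    fs: float


def extract_region_epochs(
    session: SubjectSession,
    roles: tuple[str, ...],
    region: tuple[float, float],
    window_s: float,
    preset: str | FilterSpec | None,
) -> list[Epoch]:
    """Filter the named channels over their full extent, then cut the
    region into non-overlapping epochs.

    ``preset`` may be a preset name (``eeg``/``ecg``/``emg``), an explicit
    :class:`FilterSpec`, or None for no filtering (the GSR path).
    """
    start, end = region
    if start < 0 or end > session.duration + 1e-9:
        raise ValueError(
            f"region {region} lies outside the recording (0, {session.duration:.3f})"
        )
    if isinstance(preset, str):
        preset = get_preset(preset, session.sampling_rate)

    filtered = []
    for role in roles:
        x = session.channel(role)
        filtered.append(filter_zero_phase(x, preset) if preset is not None else x)
    stack = np.vstack(filtered)

    grid = build_epoch_grid(region, window_s)
    fs = session.sampling_rate
    n_win = int(round(window_s * fs))
    epochs = []
    for s in grid:
        i0 = int(round(s * fs))
        epochs.append(Epoch(stack[:, i0 : i0 + n_win], s, window_s, tuple(roles), fs))
    return epochs


def roi_epoch_grids(session_or_timeline, window_s: float = 2.0) -> dict[str, EpochGrid]:
    """Epoch grids over the regions of interest (RS1/MIST/relax/RS2)."""
    timeline = getattr(session_or_timeline, "timeline", session_or_timeline)
    return {
        name: build_epoch_grid(region, window_s)
        for name, region in regions_of_interest(timeline).items()
    }
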