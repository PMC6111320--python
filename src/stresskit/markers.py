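"""The four per-epoch stress markers and their assembly on a 2-s grid.

* RG  -- relative gamma: EEG power in the gamma band (25-45 Hz) divided
  by power in the theta-alpha band (4-13 Hz), each averaged across the
  four frontal channels.  Rises with arousal.
* HR  -- heart rate in bpm, 60 / mean R-R interval, estimated on 10-s
  epochs from R-peaks of the band-passed ECG and spline-interpolated
  onto the 2-s grid.
* TA  -- trapezius activity: RMS of the differential EMG in the epoch,
  normalized by the RMS during the maximum-voluntary-contraction test.
* SC  -- skin conductance in Siemens, an affine map of the mean sensor
  voltage: SC = 2 * (mean voltage - 0.5) / 100000.

All markers are assembled into one table with a row per 2-s epoch of the
regions of interest (central minutes of the resting-state blocks, full
stress session, full relaxation session; 630 rows on the default
timeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import detrend_normalize, filter_zero_phase, get_preset
from .session import (
    EEG_ROLES,
    EpochGrid,
    SubjectSession,
    build_epoch_grid,
    regions_of_interest,
)

__all__ = [
    "THETA_ALPHA_BAND",
    "GAMMA_BAND",
    "band_power",
    "compute_rg",
    "detect_r_peaks",
    "compute_hr",
    "interpolate_hr",
    "differential_emg",
    "compute_ta",
    "compute_sc",
    "MvcReference",
    "HrSeries",
    "extract_markers",
    "MarkerExtractor",
]

THETA_ALPHA_BAND = (4.0, 13.0)
GAMMA_BAND = (25.0, 45.0)

MARKER_COLUMNS = ("RG", "HR", "TA", "SC")


class MarkerError(ValueError):
    """A marker is undefined for the given input (e.g. flat EEG epoch)."""


# ---------------------------------------------------------------------------
# EEG: relative gamma


def hann_periodogram(samples: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-windowed periodogram (power spectral density) on
    the last axis, after mean removal."""
    x = np.asarray(samples, float)
    n = x.shape[-1]
    w = sps.get_window("hann", n)
    xw = (x - x.mean(axis=-1, keepdims=True)) * w
    spec = np.fft.rfft(xw, axis=-1)
    pxx = np.abs(spec) ** 2 / (fs * (w * w).sum())
    if n % 2 == 0:
        pxx[..., 1:-1] *= 2.0
    else:
        pxx[..., 1:] *= 2.0
    return np.fft.rfftfreq(n, d=1.0 / fs), pxx


def _integrate_band(
    freqs: np.ndarray, pxx: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    low, high = band
    df = freqs[1] - freqs[0]
    sel = (freqs >= low - 1e-9) & (freqs < high - 1e-9)
    return pxx[..., sel].sum(axis=-1) * df


def band_power(samples: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Integrated power in ``band = [low, high)`` via a Hann periodogram.

    Spectral-density bins with centers in the half-open band are summed
    and scaled by the bin width, so for white noise the value is
    proportional to the band width.  Works on the last axis.
    """
    low, high = band
    if not 0 <= low < high or high > fs / 2:
        raise ValueError(f"band {band} not inside (0, {fs / 2}) Hz")
    freqs, pxx = hann_periodogram(samples, fs)
    return _integrate_band(freqs, pxx, band)


def compute_rg(eeg_epoch: np.ndarray, fs: float) -> float:
    """Relative gamma of one (already normalized) 4-channel EEG epoch.

    Power is estimated per channel, averaged across channels for each
    band, and the gamma / theta-alpha ratio is returned.
    """
    x = np.atleast_2d(np.asarray(eeg_epoch, float))
    gamma = band_power(x, GAMMA_BAND, fs).mean()
    theta_alpha = band_power(x, THETA_ALPHA_BAND, fs).mean()
    if theta_alpha <= 0:
        raise MarkerError("relative gamma undefined: zero theta-alpha power")
    return float(gamma / theta_alpha)


# ---------------------------------------------------------------------------
# ECG: heart rate

REFRACTORY_S = 0.25  # minimum plausible R-R interval used by the peak picker
HR_PLAUSIBLE_BPM = (20.0, 250.0)


def detect_r_peaks(ecg_filtered: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times (s) from a 16-24 Hz band-passed ECG.

    Local maxima of the signal magnitude above an adaptive threshold
    (half the 95th percentile of the magnitude over each 10-s block),
    with a 250-ms refractory period.  Returns strictly increasing times;
    empty when nothing crosses the threshold.
    """
    x = np.abs(np.asarray(ecg_filtered, float))
    n = x.size
    block = int(round(10 * fs))
    thresh = np.empty(n)
    for i0 in range(0, n, block):
        seg = x[i0 : i0 + block]
        thresh[i0 : i0 + block] = 0.5 * np.percentile(seg, 95)
    # guard against all-flat blocks producing a zero threshold
    floor = 1e-12 * (x.max() if x.max() > 0 else 1.0)
    thresh = np.maximum(thresh, floor)
    idx, _ = sps.find_peaks(x, height=thresh, distance=max(1, int(round(REFRACTORY_S * fs))))
    return idx / fs


@dataclass
class HrSeries:
    """Per-10-s-epoch mean R-R interval and heart rate (NaN = missing)."""

    grid: EpochGrid
    avrr_s: np.ndarray
    hr_bpm: np.ndarray


def compute_hr(peaks_s: np.ndarray, grid: EpochGrid) -> HrSeries:
    """Mean R-R interval and HR = 60/AvRR per 10-s epoch.

    An R-R interval is attributed to the epoch containing its onset
    (its first peak).  Epochs with no attributable interval, or with an
    implausible rate, are marked missing (NaN).
    """
    peaks = np.asarray(peaks_s, float)
    rr = np.diff(peaks)
    onsets = peaks[:-1]
    avrr = np.full(len(grid), np.nan)
    for k, (s, e) in enumerate(grid.intervals()):
        sel = (onsets >= s) & (onsets < e)
        if sel.any():
            avrr[k] = rr[sel].mean()
    hr = 60.0 / avrr
    bad = ~np.isnan(hr) & ((hr < HR_PLAUSIBLE_BPM[0]) | (hr > HR_PLAUSIBLE_BPM[1]))
    if bad.any():
        warnings.warn(f"{bad.sum()} epoch(s) with implausible heart rate marked missing")
        avrr[bad] = np.nan
        hr[bad] = np.nan
    return HrSeries(grid, avrr, hr)


def interpolate_hr(hr: HrSeries, target: EpochGrid) -> np.ndarray:
    """Interpolate 10-s heart rates onto 2-s epoch midpoints.

    A cubic spline through the (10-s midpoint, HR) knots, evaluated at
    the 2-s midpoints; beyond the first/last knot values are clamped to
    the nearest knot.  With fewer than 4 support points a linear
    interpolant is used; with fewer than 2 an error is raised.
    """
    knots_x = hr.grid.midpoints
    good = ~np.isnan(hr.hr_bpm)
    xs, ys = knots_x[good], hr.hr_bpm[good]
    if xs.size < 2:
        raise MarkerError(
            f"heart-rate interpolation needs >= 2 supported 10-s epochs, got {xs.size}"
        )
    t = np.clip(target.midpoints, xs[0], xs[-1])
    if xs.size < 4:
        return np.interp(t, xs, ys)
    return CubicSpline(xs, ys)(t)


# ---------------------------------------------------------------------------
# EMG: trapezius activity


def differential_emg(medial: np.ndarray, lateral: np.ndarray) -> np.ndarray:
    """Differential trapezius EMG: electrode closer to the backbone minus
    the electrode further from it."""
    medial = np.asarray(medial, float)
    lateral = np.asarray(lateral, float)
    if medial.shape != lateral.shape:
        raise ValueError(f"length mismatch: {medial.shape} vs {lateral.shape}")
    return medial - lateral


def _rms(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=-1))


@dataclass(frozen=True)
class MvcReference:
    """RMS of the differential EMG over the maximum-voluntary-contraction
    test window; the normalization denominator for trapezius activity."""

    rms_value: float

    def __post_init__(self) -> None:
        if not self.rms_value > 0:
            raise ValueError(f"MVC reference RMS must be > 0, got {self.rms_value}")


def compute_ta(emg_epoch: np.ndarray, mvc: MvcReference) -> float:
    """Trapezius activity: epoch RMS over MVC-test RMS."""
    return float(_rms(np.asarray(emg_epoch, float)) / mvc.rms_value)


# ---------------------------------------------------------------------------
# GSR: skin conductance

SC_OFFSET_V = 0.5
SC_SCALE = 2.0 / 100_000.0  # Siemens per volt


def compute_sc(gsr_epoch: np.ndarray) -> float:
    """Skin conductance (Siemens) from the mean sensor voltage in the
    epoch: SC = 2 * (AvVoltage - 0.5) / 100000 (e-Health sensor map)."""
    av = float(np.mean(gsr_epoch))
    sc = SC_SCALE * (av - SC_OFFSET_V)
    if sc < 0:
        warnings.warn(f"negative skin conductance ({sc:.3e} S) from mean voltage {av:.3f} V")
    return sc


# ---------------------------------------------------------------------------
# orchestration


def extract_markers(session: SubjectSession, window_s: float = 2.0) -> pd.DataFrame:
    """All four markers on the common 2-s epoch grid of the regions of
    interest.

    Returns a DataFrame with one row per epoch and columns
    ``subject_id, region, epoch_start_s, RG, HR, TA, SC``.
    """
    fs = session.sampling_rate
    tl = session.timeline
    if not tl.mvc_end > tl.mvc_start:
        raise ValueError(
            "session has no maximum-voluntary-contraction window "
            f"(mvc_start={tl.mvc_start}, mvc_end={tl.mvc_end}); "
            "the trapezius-activity marker needs one"
        )
    regions = regions_of_interest(tl)

    # EEG: filter once over the full channels
    eeg = np.vstack(
        [filter_zero_phase(session.channel(r), get_preset("eeg", fs)) for r in EEG_ROLES]
    )
    # ECG: filter + R-peaks over the full recording
    ecg = filter_zero_phase(session.channel("ECG"), get_preset("ecg", fs))
    peaks = detect_r_peaks(ecg, fs)
    # EMG: filter both electrodes, then take the differential
    emg_spec = get_preset("emg", fs)
    emg = differential_emg(
        filter_zero_phase(session.channel("EMG_medial"), emg_spec),
        filter_zero_phase(session.channel("EMG_lateral"), emg_spec),
    )
    mvc = MvcReference(float(_rms(emg[session.sample_slice(tl.mvc_start, tl.mvc_end)])))
    gsr = session.channel("GSR_voltage")

    n_win = int(round(window_s * fs))
    frames = []
    for name, region in regions.items():
        grid2 = build_epoch_grid(region, window_s)
        if len(grid2) == 0:
            continue
        i0 = np.array([int(round(s * fs)) for s in grid2])
        seg = np.stack([eeg[:, i : i + n_win] for i in i0])  # (n_ep, 4, n_win)

        norm = detrend_normalize(seg)
        freqs, pxx = hann_periodogram(norm, fs)
        gamma = _integrate_band(freqs, pxx, GAMMA_BAND).mean(axis=1)
        theta_alpha = _integrate_band(freqs, pxx, THETA_ALPHA_BAND).mean(axis=1)
        if np.any(theta_alpha <= 0):
            raise MarkerError(f"flat EEG epoch in region {name!r}: relative gamma undefined")
        rg = gamma / theta_alpha

        grid10 = build_epoch_grid(region, 10.0)
        hr = interpolate_hr(compute_hr(peaks, grid10), grid2)

        ta = np.array([compute_ta(emg[i : i + n_win], mvc) for i in i0])
        sc = np.array([compute_sc(gsr[i : i + n_win]) for i in i0])

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": session.subject_id,
                    "region": name,
                    "epoch_start_s": np.asarray(grid2.starts),
                    "RG": rg,
                    "HR": hr,
                    "TA": ta,
                    "SC": sc,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if out[list(MARKER_COLUMNS)].isna().any().any():
        raise MarkerError("marker table contains missing values after interpolation")
    return out


class MarkerExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer turning sessions into marker tables.

    ``transform`` accepts a single session or a list of sessions and
    returns the concatenated per-epoch marker table; composes with
    sklearn pipelines.
    """

    def __init__(self, window_s: float = 2.0):
        self.window_s = window_s

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X) -> pd.DataFrame:
        sessions = [X] if isinstance(X, SubjectSession) else list(X)
        return pd.concat(
            [extract_markers(s, window_s=self.window_s) for s in sessions],
            ignore_index=True,
        )
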