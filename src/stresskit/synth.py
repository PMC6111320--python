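"""Synthetic recording sessions with the statistical structure the
analysis assumes.

A latent arousal level a(t) in [0, 1] drives all four modalities: it
sits at a baseline during the resting-state blocks, ramps up gradually
over the stress task, decays exponentially once the relaxation session
starts -- quickly for the EEG/ECG/EMG-borne markers, slowly for skin
conductance (sweat is produced fast but reabsorbed slowly) -- and the
EEG profile additionally drifts back up late in the relaxation session
(boredom effect).

Modality synthesis:

* EEG: 1/f-like background plus two band-limited Gaussian noise
  carriers (theta-alpha 4-13 Hz, gamma 25-45 Hz) whose power ratio
  tracks the programmed relative gamma rg_base + rg_gain * a(t).
* ECG: Gaussian R-wave templates placed at beat times integrated from
  the instantaneous rate hr_min + a(t) * (hr_max - hr_min); the
  programmed beat times are an exact oracle for peak detection.
* EMG: band-limited (1-350 Hz) noise whose RMS is a programmed fraction
  of the maximum-voluntary-contraction RMS, split onto two electrodes
  around a common-mode term, plus an MVC burst in the MVC window.
* GSR: slowly varying sensor voltage mapped affinely from a(t) so skin
  conductance increases with arousal, plus small noise.

Per-subject additive offsets (on the programmed relative gamma, heart
rate, contraction fraction and sensor voltage) make subjects
non-exchangeable, which is what degrades leave-one-subject-out
cross-validation; ``subject_offset_scale=0`` switches them off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .session import CHANNEL_ROLES, ChannelMap, EventTimeline, SubjectSession

__all__ = [
    "SimulationParams",
    "ArousalProfile",
    "SubjectOffsets",
    "stress_profile",
    "generate_modality",
    "programmed_beat_times",
    "generate_session",
    "generate_cohort",
    "iter_cohort",
]


@dataclass(frozen=True)
class SimulationParams:
    """All tunable couplings of the synthetic cohort generator."""

    sampling_rate: float = 1000.0
    timeline: EventTimeline = field(default_factory=EventTimeline)

    # latent arousal dynamics
    baseline: float = 0.15
    peak: float = 0.9
    relax_floor: float = 0.05
    tau_fast_s: float = 30.0     # post-stress decay of EEG/ECG/EMG arousal
    tau_slow_s: float = 180.0    # post-stress decay of the skin-conductance drive
    eeg_drift_per_s: float = 0.0006  # late-relaxation upward drift (EEG only)
    eeg_drift_delay_s: float = 120.0

    # EEG couplings: programmed relative gamma = rg_base + rg_gain * a(t)
    rg_base: float = 0.6
    rg_gain: float = 1.2
    eeg_background_sd: float = 0.3
    theta_alpha_amp: float = 1.0

    # ECG couplings
    hr_min_bpm: float = 65.0
    hr_max_bpm: float = 95.0
    r_wave_width_s: float = 0.008
    ecg_noise_sd: float = 0.01

    # EMG couplings: RMS fraction of MVC = frac_base + frac_gain * a(t)
    emg_frac_base: float = 0.1
    emg_frac_gain: float = 0.4
    mvc_amp: float = 1.0
    emg_electrode_noise_sd: float = 0.02

    # GSR couplings: sensor volts = gsr_v0 + gsr_gain * a_sc(t)
    gsr_v0: float = 1.2
    gsr_gain: float = 1.5
    gsr_noise_sd_v: float = 0.01

    # slow within-subject variability: an Ornstein-Uhlenbeck drift in
    # arousal units, drawn independently per modality, emulating the
    # marker-specific fluctuations real biosignals carry on top of the
    # shared arousal drive
    slow_drift_sd: float = 0.1
    slow_drift_tau_s: float = 60.0

    # per-subject additive offsets, scaled by subject_offset_scale
    subject_offset_scale: float = 1.0
    offset_sd_rg: float = 0.12
    offset_sd_hr_bpm: float = 4.0
    offset_sd_frac: float = 0.04
    offset_sd_gsr_v: float = 0.25

    def __post_init__(self) -> None:
        if not 30.0 < self.hr_min_bpm < self.hr_max_bpm < 200.0:
            raise ValueError(
                f"heart-rate range ({self.hr_min_bpm}, {self.hr_max_bpm}) "
                "must lie within (30, 200) bpm"
            )
        base_fracs = (
            self.emg_frac_base,
            self.emg_frac_base + self.emg_frac_gain,
        )
        if not all(0.0 < f <= 1.0 for f in base_fracs):
            raise ValueError("EMG MVC fractions must stay in (0, 1]")
        volts = (self.gsr_v0, self.gsr_v0 + self.gsr_gain)
        if not all(0.5 < v < 5.0 for v in volts):
            raise ValueError("GSR sensor voltage must stay within (0.5, 5) V")

    def with_(self, **overrides) -> "SimulationParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class SubjectOffsets:
    """Additive per-subject shifts of the programmed marker levels."""

    rg: float = 0.0
    hr_bpm: float = 0.0
    frac: float = 0.0
    gsr_v: float = 0.0

    @classmethod
    def draw(cls, params: SimulationParams, rng: np.random.Generator) -> "SubjectOffsets":
        s = params.subject_offset_scale
        u = rng.uniform(-1.0, 1.0, size=4)
        return cls(
            rg=float(u[0] * params.offset_sd_rg * s),
            hr_bpm=float(u[1] * params.offset_sd_hr_bpm * s),
            frac=float(u[2] * params.offset_sd_frac * s),
            gsr_v=float(u[3] * params.offset_sd_gsr_v * s),
        )


@dataclass(frozen=True)
class ArousalProfile:
    """Latent arousal level on a 1-s grid, interpolated in between."""

    times_s: np.ndarray
    values: np.ndarray
    modality: str

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.times_s, self.values)


def stress_profile(
    timeline: EventTimeline, params: SimulationParams, modality: str
) -> ArousalProfile:
    """Modality-specific arousal profile over the whole recording.

    All modalities share the baseline and the gradual stress ramp; the
    skin-conductance drive uses the slow decay constant; the EEG profile
    adds a late upward drift during the relaxation session.
    """
    modality = modality.lower()
    if modality not in ("eeg", "ecg", "emg", "gsr"):
        raise ValueError(f"unknown modality {modality!r}")
    tl = timeline
    p = params
    tau = p.tau_slow_s if modality == "gsr" else p.tau_fast_s

    t = np.arange(0.0, math.ceil(tl.span) + 1.0)
    a = np.full_like(t, p.baseline)

    ramp = (t >= tl.mist_train_start) & (t <= tl.mist_end)
    frac = (t[ramp] - tl.mist_train_start) / (tl.mist_end - tl.mist_train_start)
    a[ramp] = p.baseline + frac * (p.peak - p.baseline)

    hold = (t > tl.mist_end) & (t <= tl.relax_start)
    a[hold] = p.peak

    relax = (t > tl.relax_start) & (t <= tl.relax_end)
    a[relax] = p.relax_floor + (p.peak - p.relax_floor) * np.exp(
        -(t[relax] - tl.relax_start) / tau
    )
    if modality == "eeg" and p.eeg_drift_per_s > 0:
        drift = p.eeg_drift_per_s * np.clip(
            t[relax] - tl.relax_start - p.eeg_drift_delay_s, 0.0, None
        )
        a[relax] = a[relax] + drift

    after = t > tl.relax_end
    a_end = a[np.searchsorted(t, tl.relax_end)]
    a[after] = p.baseline + (a_end - p.baseline) * np.exp(-(t[after] - tl.relax_end) / tau)

    return ArousalProfile(t, np.clip(a, 0.0, 1.0), modality)


# ---------------------------------------------------------------------------
# band-limited Gaussian noise synthesised directly in the frequency domain


def _spectral_noise(
    n: int,
    fs: float,
    amp_of_freq,
    rng: np.random.Generator,
    n_rows: int = 1,
) -> np.ndarray:
    """Unit-RMS Gaussian noise rows with spectral amplitude ``amp_of_freq``.

    Synthesised directly in the frequency domain (iid complex Gaussian
    coefficients shaped by the amplitude profile) on a padded fast FFT
    length, then truncated to ``n`` samples and normalized per row.
    """
    m = sfft.next_fast_len(n, real=True)
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    amp = np.asarray(amp_of_freq(freqs), np.float32)
    sel = np.flatnonzero(amp > 0)
    # single precision throughout: the synthesised noise is consumed at
    # physiological SNRs where float32 resolution is far below the noise
    spec = np.zeros((n_rows, freqs.size), dtype=np.complex64)
    spec[:, sel] = amp[sel] * (
        rng.standard_normal((n_rows, sel.size), dtype=np.float32)
        + 1j * rng.standard_normal((n_rows, sel.size), dtype=np.float32)
    )
    x = sfft.irfft(spec, n=m, axis=-1)[:, :n]
    x /= x.std(axis=-1, keepdims=True)
    return x


def _band_noise(
    n: int, fs: float, low: float, high: float, rng: np.random.Generator, n_rows: int = 1
) -> np.ndarray:
    """Unit-RMS Gaussian noise rows confined to the band [low, high) Hz."""
    return _spectral_noise(
        n, fs, lambda f: ((f >= low) & (f < high)).astype(float), rng, n_rows
    )


# IIR approximation of a 1/f spectral shaper (Kasdin-style pole-zero fit)
_PINK_B = (0.049922035, -0.095993537, 0.050612699, -0.004408786)
_PINK_A = (1.0, -2.494956002, 2.017265875, -0.522189400)


def _pink_noise(n: int, fs: float, rng: np.random.Generator, n_rows: int = 1) -> np.ndarray:
    """Unit-RMS 1/f-like noise rows (spectral density ~ 1/f)."""
    from scipy.signal import lfilter

    white = rng.standard_normal((n_rows, n), dtype=np.float32)
    x = lfilter(
        np.asarray(_PINK_B, np.float32), np.asarray(_PINK_A, np.float32), white, axis=-1
    )
    return x / x.std(axis=-1, keepdims=True)


def programmed_beat_times(
    profile: ArousalProfile, params: SimulationParams, offsets: SubjectOffsets | None = None
) -> np.ndarray:
    """Exact beat times implied by the instantaneous programmed heart
    rate; the oracle for R-peak detection tests."""
    off = offsets or SubjectOffsets()
    # offsets saturate at the plausible physiological range
    hr_min = float(np.clip(params.hr_min_bpm + off.hr_bpm, 35.0, 185.0))
    span = float(profile.times_s[-1])

    def rate(t: float) -> float:
        return float(
            np.clip(hr_min + profile(t) * (params.hr_max_bpm - params.hr_min_bpm), 30.0, 200.0)
        )

    beats = []
    t = 0.5  # first beat shortly after recording start
    while t < span:
        beats.append(t)
        t += 60.0 / rate(t)
    return np.asarray(beats)


def generate_modality(
    modality: str,
    profile: ArousalProfile,
    params: SimulationParams,
    seed: int | np.random.Generator,
    offsets: SubjectOffsets | None = None,
    n_channels: int = 1,
) -> np.ndarray:
    """One modality's raw sample sequence over the full timeline.

    Returns a 1-D array for ``eeg`` (or an (n_channels, n) array when
    several electrodes are requested at once), a 1-D array for ``ecg``
    and ``gsr``, and a (2, n) array (medial, lateral electrode) for
    ``emg``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    off = offsets or SubjectOffsets()
    p = params
    fs = p.sampling_rate
    n = int(round(float(profile.times_s[-1]) * fs))
    t = np.arange(n) / fs
    a = profile(t)
    modality = modality.lower()

    if modality == "eeg":
        rg = np.clip(p.rg_base + off.rg + p.rg_gain * a, 0.05, None).astype(np.float32)
        # carriers sit 1.5 Hz inside the analysis bands (theta-alpha
        # 4-13 Hz, gamma 25-45 Hz) so short-epoch spectral leakage stays
        # within the band and the programmed power ratio is measurable
        ta_carrier = _band_noise(n, fs, 5.5, 11.5, rng, n_rows=n_channels)
        g_carrier = _band_noise(n, fs, 26.5, 43.5, rng, n_rows=n_channels)
        background = p.eeg_background_sd * _pink_noise(n, fs, rng, n_rows=n_channels)
        out = (
            p.theta_alpha_amp * ta_carrier
            + p.theta_alpha_amp * np.sqrt(rg) * g_carrier
            + background
        )
        return out if n_channels > 1 else out[0]

    if modality == "ecg":
        beats = programmed_beat_times(profile, p, off)
        x = p.ecg_noise_sd * rng.standard_normal(n, dtype=np.float32)
        half = int(round(4 * p.r_wave_width_s * fs))
        k = np.arange(-half, half + 1)
        template = np.exp(-0.5 * (k / (p.r_wave_width_s * fs)) ** 2)
        for b in beats:
            i = int(round(b * fs))
            lo, hi = max(0, i - half), min(n, i + half + 1)
            x[lo:hi] += template[lo - (i - half) : hi - (i - half)]
        return x

    if modality == "emg":
        frac = np.clip(p.emg_frac_base + off.frac + p.emg_frac_gain * a, 0.02, 1.0)
        # full-strength burst during the MVC test window
        tl_ = p.timeline
        in_mvc = (t >= tl_.mvc_start) & (t < tl_.mvc_end)
        envelope = (np.where(in_mvc, 1.0, frac) * p.mvc_amp).astype(np.float32)
        diff = envelope * _band_noise(n, fs, 1.0, 350.0, rng)[0]
        common = 0.05 * p.mvc_amp * _band_noise(n, fs, 1.0, 350.0, rng)[0]
        noise = np.float32(p.emg_electrode_noise_sd * p.mvc_amp)
        medial = diff / 2.0 + common + noise * rng.standard_normal(n, dtype=np.float32)
        lateral = -diff / 2.0 + common + noise * rng.standard_normal(n, dtype=np.float32)
        return np.vstack([medial, lateral])

    if modality == "gsr":
        v = (
            p.gsr_v0
            + off.gsr_v
            + p.gsr_gain * a
            + p.gsr_noise_sd_v * rng.standard_normal(n, dtype=np.float32)
        )
        return np.clip(v, 0.55, 4.95)

    raise ValueError(f"unknown modality {modality!r}")


def _drifted(
    profile: ArousalProfile, params: SimulationParams, rng: np.random.Generator
) -> ArousalProfile:
    """Add a mean-reverting slow drift to an arousal profile."""
    sd, tau = params.slow_drift_sd, params.slow_drift_tau_s
    if sd <= 0:
        return profile
    n = profile.values.size
    rho = math.exp(-1.0 / tau)  # profile grid is 1 s
    innov = sd * math.sqrt(1 - rho**2) * rng.standard_normal(n)
    d = np.empty(n)
    d[0] = sd * rng.standard_normal()
    for k in range(1, n):
        d[k] = rho * d[k - 1] + innov[k]
    return ArousalProfile(
        profile.times_s, np.clip(profile.values + d, 0.0, 1.0), profile.modality
    )


def generate_session(
    subject_id: str,
    params: SimulationParams,
    seed: int | np.random.Generator,
    offsets: SubjectOffsets | None = None,
) -> SubjectSession:
    """One complete 8-channel synthetic session.

    Each modality's arousal profile receives its own slow drift, so the
    four markers share the arousal trajectory but are not deterministic
    functions of one another."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    off = offsets or SubjectOffsets()
    tl = params.timeline
    base = {m: stress_profile(tl, params, m) for m in ("eeg", "ecg", "emg", "gsr")}
    profiles = {m: _drifted(p, params, rng) for m, p in base.items()}

    channels = np.empty((8, int(round(math.ceil(tl.span) * params.sampling_rate))))
    cmap = ChannelMap(CHANNEL_ROLES)
    eeg = generate_modality("eeg", profiles["eeg"], params, rng, off, n_channels=4)
    for k, role in enumerate(("EEG_Fp1", "EEG_Fp2", "EEG_F3", "EEG_F4")):
        channels[cmap.index_of(role)] = eeg[k]
    channels[cmap.index_of("ECG")] = generate_modality("ecg", profiles["ecg"], params, rng, off)
    emg = generate_modality("emg", profiles["emg"], params, rng, off)
    channels[cmap.index_of("EMG_medial")] = emg[0]
    channels[cmap.index_of("EMG_lateral")] = emg[1]
    channels[cmap.index_of("GSR_voltage")] = generate_modality(
        "gsr", profiles["gsr"], params, rng, off
    )

    # self-report reflects the underlying arousal, not one modality's drift
    a = base["ecg"]
    spsl = tuple(int(np.clip(round(4 * a(tp)), 0, 4)) for tp in (tl.t1, tl.t2, tl.t3))
    return SubjectSession(
        subject_id=subject_id,
        sampling_rate=params.sampling_rate,
        channels=channels,
        channel_map=cmap,
        timeline=tl,
        spsl=spsl,
    )


def generate_cohort(
    n_subjects: int = 10,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> list[SubjectSession]:
    """A reproducible cohort of synthetic subjects.

    The seed fans out deterministically: per-subject offsets are drawn
    from one cohort-level stream, and each subject's signal noise comes
    from an independently spawned child stream, so cohorts of different
    sizes share their leading subjects.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    params = params or SimulationParams()
    return list(iter_cohort(n_subjects, params, seed))


def iter_cohort(n_subjects: int = 10, params: SimulationParams | None = None, seed: int = 0):
    """Like :func:`generate_cohort` but yields subjects one at a time,
    so large cohorts need not be held in memory at once."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    params = params or SimulationParams()
    children = np.random.SeedSequence(seed).spawn(n_subjects + 1)
    offset_rng = np.random.default_rng(children[0])
    for j in range(n_subjects):
        off = SubjectOffsets.draw(params, offset_rng)
        yield generate_session(
            f"S{j + 1:02d}", params, np.random.default_rng(children[j + 1]), off
        )
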