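"""The four stress markers against independent oracles.

Expected values come from closed forms (flat-spectrum band-power
ratios, RMS of sinusoids, the affine conductance map) or from the
generator's programmed quantities (beat times, MVC fractions, band
power ratios), never from the code under test.
"""

import numpy as np
import pandas as pd
import pytest

import stresskit as sk
from stresskit.markers import (
    GAMMA_BAND,
    THETA_ALPHA_BAND,
    MarkerError,
    MvcReference,
    band_power,
    compute_hr,
    compute_rg,
    compute_sc,
    compute_ta,
    detect_r_peaks,
    differential_emg,
    interpolate_hr,
)
from stresskit.preprocess import filter_zero_phase, get_preset
from stresskit.session import build_epoch_grid

FS = 1000.0


def _sine(freq, dur=2.0, amp=1.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestBandPower:
    def test_spectral_concentration(self):
        x = _sine(10.0)
        assert band_power(x, THETA_ALPHA_BAND, FS) > 1000 * band_power(x, GAMMA_BAND, FS)

    def test_white_noise_ratio_tracks_bandwidth(self):
        """Flat spectrum: band power ~ bandwidth, ratio (45-25)/(13-4)."""
        x = np.random.default_rng(0).standard_normal(2_000_000)
        ratio = band_power(x, GAMMA_BAND, FS) / band_power(x, THETA_ALPHA_BAND, FS)
        assert ratio == pytest.approx(20 / 9, rel=0.02)

    def test_equal_amplitude_sines_equal_power(self):
        x = _sine(10.0) + _sine(30.0)
        pg = band_power(x, GAMMA_BAND, FS)
        pta = band_power(x, THETA_ALPHA_BAND, FS)
        assert pg == pytest.approx(pta, rel=0.01)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(100), (100.0, 600.0), FS)


class TestRelativeGamma:
    def test_pure_gamma_dominates(self):
        x = np.vstack([_sine(30.0) + 1e-3 * _sine(10.0)] * 4)
        assert compute_rg(x, FS) > 100

    def test_white_noise_long_run_expectation(self):
        """Over many epochs of white noise RG averages to 20/9."""
        rng = np.random.default_rng(1)
        vals = [compute_rg(rng.standard_normal((4, 2000)), FS) for _ in range(300)]
        assert np.mean(vals) == pytest.approx(20 / 9, rel=0.05)

    def test_balanced_mixture_gives_unity(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(50):
            phase = rng.uniform(0, 2 * np.pi, (4, 2))
            x = np.vstack(
                [_sine(10.0, phase=p1) + _sine(30.0, phase=p2) for p1, p2 in phase]
            )
            vals.append(compute_rg(x, FS))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_amplitude_scaling_invariance(self):
        x = np.random.default_rng(3).standard_normal((4, 2000))
        assert compute_rg(137.0 * x, FS) == pytest.approx(compute_rg(x, FS), rel=1e-9)

    def test_flat_epoch_rejected(self):
        with pytest.raises(MarkerError):
            compute_rg(np.zeros((4, 2000)), FS)


def _programmed_ecg(rate_bpm, params=None, seed=0):
    """Synthetic ECG at a constant programmed rate plus its exact beat
    times, band-passed for peak detection."""
    params = params or sk.SimulationParams(hr_min_bpm=rate_bpm, hr_max_bpm=rate_bpm + 1e-9)
    tl = params.timeline
    profile = sk.stress_profile(tl, params, "ecg")
    flat = sk.synth.ArousalProfile(profile.times_s, np.zeros_like(profile.values), "ecg")
    raw = sk.generate_modality("ecg", flat, params, seed)
    beats = sk.programmed_beat_times(flat, params)
    return filter_zero_phase(raw, get_preset("ecg", FS)), beats


class TestRPeaks:
    def test_beats_recovered_within_10ms(self):
        ecg, beats = _programmed_ecg(60.0)
        det = detect_r_peaks(ecg, FS)
        sel = beats[(beats > 5) & (beats < beats[-1] - 5)]
        assert abs(len(det) - len(beats)) <= 2
        # match each programmed beat to the nearest detection
        err = np.array([np.min(np.abs(det - b)) for b in sel])
        assert np.max(err) <= 0.010

    @pytest.mark.parametrize("rate", [50.0, 70.0, 100.0, 140.0])
    def test_rate_recovery_within_1_bpm(self, rate):
        ecg, _ = _programmed_ecg(rate)
        det = detect_r_peaks(ecg, FS)
        est = 60.0 / np.mean(np.diff(det))
        assert est == pytest.approx(rate, abs=1.0)

    def test_flat_signal_yields_no_peaks(self):
        assert detect_r_peaks(np.zeros(20_000), FS).size == 0

    def test_peak_times_strictly_increasing_with_refractory(self):
        ecg, _ = _programmed_ecg(120.0)
        det = detect_r_peaks(ecg, FS)
        assert np.all(np.diff(det) >= 0.25)


class TestHeartRate:
    @pytest.mark.parametrize("rr, hr", [(1.0, 60.0), (0.8, 75.0)])
    def test_constant_rr(self, rr, hr):
        peaks = np.arange(0.3, 60, rr)
        series = compute_hr(peaks, build_epoch_grid((0, 60), 10.0))
        assert np.allclose(series.hr_bpm, hr)

    def test_alternating_rr_uses_mean_interval(self):
        # RR alternates 0.6/1.0 -> AvRR 0.8 -> 75 bpm
        rr = np.tile([0.6, 1.0], 40)
        peaks = np.concatenate([[0.2], 0.2 + np.cumsum(rr)])
        series = compute_hr(peaks, build_epoch_grid((0, 60), 10.0))
        assert np.allclose(series.avrr_s, 0.8, atol=0.02)
        assert np.allclose(series.hr_bpm, 75.0, atol=2.0)

    def test_sparse_epoch_marked_missing(self):
        peaks = np.array([2.0, 2.9, 25.0, 25.8])  # nothing in [10, 20)
        series = compute_hr(peaks, build_epoch_grid((0, 30), 10.0))
        assert np.isnan(series.hr_bpm[1])


class TestHrInterpolation:
    def _series(self, values, region=(0, 60)):
        grid = build_epoch_grid(region, 10.0)
        return sk.markers.HrSeries(grid, 60.0 / np.asarray(values), np.asarray(values, float))

    def test_constant_reproduced_exactly(self):
        out = interpolate_hr(self._series([72] * 6), build_epoch_grid((0, 60), 2.0))
        assert np.allclose(out, 72.0)

    def test_linear_ramp_reproduced(self):
        knots = np.linspace(60, 90, 6)
        out = interpolate_hr(self._series(knots), build_epoch_grid((0, 60), 2.0))
        mids = build_epoch_grid((0, 60), 2.0).midpoints
        expected = np.interp(np.clip(mids, 5, 55), np.linspace(5, 55, 6), knots)
        assert np.allclose(out, expected, atol=1e-9)

    def test_sinusoid_matches_dense_spline_oracle(self):
        from scipy.interpolate import CubicSpline

        grid10 = build_epoch_grid((0, 120), 10.0)
        hr = 70 + 8 * np.sin(2 * np.pi * grid10.midpoints / 60.0)
        out = interpolate_hr(self._series(hr, (0, 120)), build_epoch_grid((0, 120), 2.0))
        mids = np.clip(build_epoch_grid((0, 120), 2.0).midpoints,
                       grid10.midpoints[0], grid10.midpoints[-1])
        oracle = CubicSpline(grid10.midpoints, hr)(mids)
        assert np.max(np.abs(out - oracle)) < 1e-9

    def test_sparse_support_falls_back_to_linear(self):
        # 3 usable knots: cubic spline unsupported, linear interpolant used
        vals = [60.0, np.nan, 70.0, np.nan, np.nan, 80.0]
        out = interpolate_hr(self._series(vals), build_epoch_grid((0, 60), 2.0))
        mids = np.clip(build_epoch_grid((0, 60), 2.0).midpoints, 5, 55)
        expected = np.interp(mids, [5, 25, 55], [60, 70, 80])
        assert np.allclose(out, expected)

    def test_too_few_knots_rejected(self):
        with pytest.raises(MarkerError, match=">= 2"):
            interpolate_hr(self._series([np.nan] * 5 + [70]), build_epoch_grid((0, 60), 2.0))


class TestEmg:
    def test_differential_identities(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert np.all(differential_emg(x, x) == 0.0)
        assert np.array_equal(differential_emg(x, np.zeros(100)), x)
        assert np.allclose(differential_emg(x, -x), 2 * x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            differential_emg(np.zeros(10), np.zeros(11))

    def test_ta_self_ratio_and_homogeneity(self):
        seg = np.random.default_rng(1).standard_normal(5000)
        mvc = MvcReference(float(np.sqrt(np.mean(seg**2))))
        assert compute_ta(seg, mvc) == pytest.approx(1.0)
        assert compute_ta(0.5 * seg, mvc) == pytest.approx(0.5)

    def test_ta_sine_amplitude_ratio(self):
        # RMS of a sinusoid is amp/sqrt(2), so TA = a/b exactly
        a, b = 0.3, 1.2
        mvc = MvcReference(b / np.sqrt(2))
        epoch = _sine(50.0, amp=a)
        assert compute_ta(epoch, mvc) == pytest.approx(a / b, rel=1e-3)

    def test_zero_mvc_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            MvcReference(0.0)

    def test_programmed_fraction_recovered(self):
        """Generator programmed at half MVC: TA on 2-s epochs averages
        to 0.5 within 5%."""
        params = sk.SimulationParams(emg_frac_base=0.5, emg_frac_gain=0.0)
        tl = params.timeline
        profile = sk.stress_profile(tl, params, "emg")
        med, lat = sk.generate_modality("emg", profile, params, 7)
        spec = get_preset("emg", FS)
        diff = filter_zero_phase(med, spec) - filter_zero_phase(lat, spec)
        i0, i1 = int(tl.mvc_start * FS), int(tl.mvc_end * FS)
        mvc = MvcReference(float(np.sqrt(np.mean(diff[i0:i1] ** 2))))
        grid = build_epoch_grid((tl.mist_train_start, tl.mist_train_start + 60), 2.0)
        tas = [
            compute_ta(diff[int(s * FS) : int(s * FS) + 2000], mvc) for s in grid
        ]
        assert np.mean(tas) == pytest.approx(0.5, rel=0.05)


class TestSkinConductance:
    @pytest.mark.parametrize(
        "volts, sc", [(0.5, 0.0), (1.0, 1e-5), (0.75, 5e-6)]
    )
    def test_affine_map_values(self, volts, sc):
        assert compute_sc(np.full(2000, volts)) == pytest.approx(sc, abs=1e-12)

    def test_slope_is_2e_minus_5_exactly(self):
        v = np.random.default_rng(0).uniform(0.6, 3.0, 50)
        scs = np.array([compute_sc(np.full(10, vi)) for vi in v])
        slope = np.polyfit(v, scs, 1)[0]
        assert slope == pytest.approx(2.0 / 100_000.0, rel=1e-12)

    def test_negative_conductance_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert compute_sc(np.full(10, 0.2)) < 0


class TestExtractMarkers:
    def test_full_table_shape_and_completeness(self, one_subject_markers):
        m = one_subject_markers
        assert len(m) == 630
        assert list(m.groupby("region").size()[["rs1", "mist", "relax", "rs2"]]) == [
            30, 270, 300, 30,
        ]
        assert not m[["RG", "HR", "TA", "SC"]].isna().any().any()
        assert (m["RG"] > 0).all() and (m["TA"] >= 0).all()
        assert m["HR"].between(20, 250).all()

    def test_missing_mvc_window_rejected(self, one_subject):
        import dataclasses

        tl = dataclasses.replace(one_subject.timeline, mvc_end=one_subject.timeline.mvc_start)
        sess = sk.SubjectSession(
            "x", one_subject.sampling_rate, one_subject.channels, timeline=tl
        )
        with pytest.raises(ValueError, match="mvc_start"):
            sk.extract_markers(sess)

    def test_deterministic(self, one_subject, one_subject_markers):
        again = sk.extract_markers(one_subject)
        pd.testing.assert_frame_equal(again, one_subject_markers)

    def test_transformer_wrapper_matches_function(self, one_subject, one_subject_markers):
        out = sk.MarkerExtractor().fit_transform(one_subject)
        pd.testing.assert_frame_equal(out, one_subject_markers)


def test_programmed_rg_recovered_without_background():
    """EEG with gamma:theta-alpha power programmed 2:1 and no 1/f
    background: RG averages to 2 over many epochs."""
    params = sk.SimulationParams(rg_base=2.0, rg_gain=0.0, eeg_background_sd=0.0)
    tl = params.timeline
    profile = sk.stress_profile(tl, params, "eeg")
    x = sk.generate_modality("eeg", profile, params, 11)
    filt = filter_zero_phase(x, get_preset("eeg", FS))
    from stresskit.preprocess import detrend_normalize

    grid = build_epoch_grid((tl.mist_train_start, tl.mist_end), 2.0)
    vals = []
    for s in grid:
        ep = detrend_normalize(filt[int(s * FS) : int(s * FS) + 2000])
        vals.append(
            band_power(ep, GAMMA_BAND, FS) / band_power(ep, THETA_ALPHA_BAND, FS)
        )
    assert np.mean(vals) == pytest.approx(2.0, rel=0.05)
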