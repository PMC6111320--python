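# Methods

## The measurement problem

Psychosocial stress leaves simultaneous traces in several biosignals:
frontal EEG shifts power toward the gamma band, the heart accelerates,
the trapezius muscle tenses, and the palmar skin conducts better as
sweat glands activate. `stresskit` implements the offline analysis for
a protocol in which a subject performs a 5-s maximum voluntary
contraction (MVC) of the trapezius, rests with closed eyes for 2 min
(RS1), undergoes a mental-arithmetic stress task (3 min training + 6
min task with adaptive time pressure), relaxes for 10 min, and rests
again (RS2), while eight channels (4 frontal EEG, 1 ECG, 2 trapezius
EMG, 1 GSR sensor voltage) are recorded at 1000 samples/s. A
self-perceived stress rating (0–4) is collected after RS1, after the
task and after relaxation.

## Markers

All markers live on a common grid of non-overlapping 2-s epochs over
the *regions of interest*: the central minute of each resting-state
block, the full stress session and the full relaxation session (30 +
270 + 300 + 30 = 630 epochs on the default timeline). Epochs are
half-open intervals; sample index = round(t·fs); trailing partial
epochs are dropped (floor semantics), which is what makes 120 s of data
yield exactly 60 epochs.

* **Relative gamma (RG).** EEG is zero-phase band-passed 1–48 Hz
  (Butterworth order 4), cut into 2-s epochs, linearly detrended and
  z-scored per channel. Power is estimated per channel with a
  Hann-windowed periodogram (0.5 Hz resolution) and integrated over the
  half-open bands [4, 13) Hz (theta–alpha) and [25, 45) Hz (gamma);
  band powers are averaged across the four channels and
  RG = gamma / theta–alpha. Integrated (not per-bin mean) power makes
  the flat-spectrum limit equal the bandwidth ratio 20/9.
* **Heart rate (HR).** ECG is band-passed 16–24 Hz (order 2) to
  sharpen the QRS complex. R-peaks are local maxima of the magnitude
  above an adaptive threshold (half the 95th percentile over 10-s
  blocks) with a 250-ms refractory period. Per 10-s epoch, AvRR is the
  mean of the R–R intervals whose onset lies in the epoch and
  HR = 60/AvRR; rates outside 20–250 bpm are treated as missing and
  excluded from interpolation support rather than zero-filled. A cubic
  spline through the 10-s epoch midpoints is evaluated at the 2-s
  midpoints, clamped to the first/last knot beyond the support; under
  4 knots the interpolant degrades to linear.
* **Trapezius activity (TA).** Both EMG electrodes are band-passed
  1–350 Hz (order 2); the differential signal is medial − lateral
  (closer to the backbone minus further). TA = RMS(2-s epoch) /
  RMS(full 5-s MVC window).
* **Skin conductance (SC).** The GSR channel carries the sensor's
  analogue voltage; SC = 2·(mean voltage − 0.5)/100 000 Siemens, the
  sensor platform's affine calibration, applied verbatim (negative
  values are emitted with a warning rather than clipped).

Filtering always precedes segmentation, on the full continuous
channel, so epoch interiors are free of warm-up transients. "Order"
is the scipy design order (`butter(order, ...)`), applied forward and
backward (`sosfiltfilt`), so the effective magnitude response is the
squared design response with zero phase lag.

## Group statistics

For visualization-grade group curves, each subject's marker series is
z-scored over the regions-of-interest extent, smoothed with a centered
10-sample moving average (window shrinks at the edges), then averaged
across subjects with the SEM. Pairwise Pearson correlations between
the smoothed grand-average curves carry Fisher-z 95% intervals,
tanh(atanh(r) ± 1.96/√(n−3)), with n the number of epoch pairs (630);
smoothing-induced autocorrelation is deliberately not corrected for.

Paired t-tests (α = 0.05, two-sided, no multiple-testing correction)
compare per-subject mean marker values between three 30-s windows: the
end of RS1, the end of the stress session, and the second-to-last 30 s
of relaxation. Because only the central minute of a resting-state
block is processed, the literal "last 30 s of RS1" holds no processed
epochs; the test helper therefore uses the last 30 s of the processed
RS1 segment (the stress and relaxation windows are unaffected). The
self-perceived ratings are compared pairwise across the three question
points with the same paired test; identical-difference triples are
flagged degenerate (infinite t) rather than crashing.

## Classification

Three classes: *stress* = minutes 7–8 of the stress session counted
from training onset (inside the task's final third), *relax* = minutes
2–3 of the relaxation session, *neutral* = the central minute of each
resting-state block — 60 two-second epochs per class, 180 per subject.
The classifier is a linear discriminant with per-class means, pooled
within-class covariance and equal priors (the design is balanced). A
ridge of 1e-6 · trace/dim on the covariance diagonal keeps degenerate
folds (e.g. duplicated features) solvable. Ties break deterministically
in the fixed order stress < relax < neutral. Features enter as raw
marker values with no per-subject normalization — which is exactly why
leave-one-subject-out degrades when subjects carry idiosyncratic
offsets, while leave-one-epoch-out within a subject does not.

Accuracy is successes/n with the normal-approximation binomial 95%
interval, half-width 1.96·√(p(1−p)/n); tables render integer percent
with half-up rounding.

## The synthetic cohort

No recordings ship with the package; a generator produces sessions
with the statistical structure the analysis assumes. A latent arousal
level a(t) ∈ [0, 1] is piecewise: baseline 0.15 at rest; a linear ramp
to 0.9 across the stress session (stress builds gradually); an
exponential decay after relaxation onset with time constant 30 s for
the EEG/ECG/EMG-borne markers but 180 s for the skin-conductance drive
(sweat is produced quickly and reabsorbed slowly); and, for EEG only, a
slow upward drift (6e-4 /s after a 120-s delay) late in relaxation,
mimicking rising boredom-related gamma.

Couplings (defaults chosen as round physiological numbers):

| quantity | mapping | default |
|---|---|---|
| relative gamma | rg = 0.6 + 1.2·a(t) | gamma-carrier amplitude √rg × theta–alpha amplitude |
| heart rate | 65 + 30·a(t) bpm | Gaussian R-wave templates (σ = 8 ms) at integrated beat times |
| EMG RMS | (0.1 + 0.4·a(t)) × MVC RMS | band-limited 1–350 Hz noise, MVC burst at full amplitude |
| GSR voltage | 1.2 + 1.5·a(t) V | clipped to the sensor's 0.5–5 V range |

EEG channels are 1/f-like background (σ = 0.3) plus two band-limited
Gaussian carriers synthesized in the frequency domain. Carriers sit
1.5 Hz inside the analysis bands (5.5–11.5 and 26.5–43.5 Hz) so that
short-epoch spectral leakage stays within the band and the programmed
power ratio is recoverable by the 2-s periodogram. Beat times are
integrated from the instantaneous programmed rate and are an exact
oracle for R-peak detection; effective rates are clipped to 30–200 bpm
so extreme subject offsets stay physiological.

Per-subject offsets (additive shifts of the programmed rg, heart-rate
floor, MVC fraction and sensor voltage; uniform draws scaled by
`subject_offset_scale`) make subjects non-exchangeable. Scale 0 gives
exchangeable subjects; the default scale 1 gives mild idiosyncrasy
(leave-one-subject-out degrades but stays above chance); at large
scales (≈25, where offsets dominate the class separation) held-out
subjects' feature clouds are disjoint from the training cohort and
leave-one-subject-out collapses to the 3-class chance level of 1/3 —
when every epoch of a held-out subject lands on the same side of the
discriminant, exactly one class (60 of 180 epochs) is predicted.

What the generator does *not* emulate: eye-blink/motion artifacts,
ECG morphology beyond the R wave, heart-rate variability structure,
electrode impedance drift, or any coupling noise between modalities
beyond the shared arousal drive. Passing tests therefore demonstrate
that the pipeline recovers what it is designed to measure under clean,
known dynamics — not that it is robust to artifact-laden field
recordings.

## Numerical and design choices

* Periodogram bands are half-open [low, high), which both avoids
  double-counting shared edges and makes the white-noise band-power
  ratio exactly the bandwidth ratio at 0.5 Hz resolution.
* Degenerate inputs are guarded, not fatal: constant epochs z-score to
  zeros (warning), empty 10-s heart-rate epochs become missing values,
  zero-variance nonzero t-test differences flag `degenerate`.
* The moving average is centered with edge shrinkage, preserving event
  alignment in group curves.
* Seeds fan out via `SeedSequence(seed).spawn`: child 0 drives subject
  offsets, child j+1 drives subject j's signal noise, so cohorts of
  different sizes share their leading subjects.
* Problem sizes in the shipped test battery: 20 independent 10-subject
  cohorts for the default-dynamics checks and 10 cohorts for the
  disjoint-offset regime, chosen to average over seed-to-seed
  variation in the stochastic assertions.
* Native session files are plain CSV/JSON with 17-significant-digit
  floats, so write → read is bit-exact and fixtures are diffable. EDF
  import is read-only and matches channel labels case-insensitively.

## Known limitations

* The adaptive R-peak threshold assumes the QRS dominates the 16–24 Hz
  band; pathological ECG or severe artifacts would need a different
  detector.
* Correlations between grand-average curves ignore the autocorrelation
  introduced by smoothing; the reported n (epoch pairs) overstates the
  effective sample size.
* Synthetic markers are far cleaner than field recordings; accuracy
  figures on synthetic cohorts characterize the pipeline, not human
  physiology.
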