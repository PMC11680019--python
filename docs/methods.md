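# Methods

## The measurement problem

A finger photoplethysmogram (PPG) measured simultaneously at a green
(~525 nm) and a near-infrared (~940 nm) wavelength carries information
from two different tissue depths: green light is absorbed within the
superficial capillary bed, near-infrared light penetrates to the deeper
arterioles. Two quantities derived from these traces index peripheral
(arteriole-to-capillary) hemodynamics:

* **1/FWHM_VPG** — the reciprocal full width at half maximum of the
  dominant (systolic) peak of the velocity plethysmogram (VPG, the
  first time-derivative of the PPG). A steeper upstroke gives a
  narrower VPG peak and a larger 1/FWHM_VPG; the quantity rises and
  falls with distal blood pressure.
* **Green-vs-NIR a-wave delay** — the lag of the green-channel
  acceleration plethysmogram (APG, second derivative) a-wave peak
  behind the near-infrared one, interpreted as the pulse transit time
  from arterioles to capillaries. Longer delays indicate a slower
  peripheral pulse wave (lower distal pulse pressure, by the
  Bramwell–Hill relation PWV² = ΔP·V/(ρ·ΔV)).

In the clinical comparison this package is built around, the diabetes
group shows lower 1/FWHM_VPG (mean 5.6 1/s, range 4.1–9.6) and longer
delay (mean 0.028 s, range 0.006–0.073) than the control group
(7.9 1/s, 5.2–14.1; 0.012 s, 0.003–0.021).

## Processing chain

1. **Band-pass filter** 0.5–20 Hz, 2nd-order Butterworth, applied
   forward-backward (zero phase) with identical coefficients on every
   channel. Zero phase is essential: the delays of interest are
   3–73 ms, and any phase distortion applied asymmetrically would bias
   them. The order/realization are engineering choices (the band edges
   are the published ones); both are configurable.
2. **Derivatives.** VPG and APG are central differences scaled by the
   sampling rate, each followed by a centered moving average (default
   50 ms, odd sample count, reflection-padded). Symmetric kernels add
   no timing bias and cancel between channels.
3. **Beat segmentation.** Systolic upstrokes are detected as dominant
   VPG maxima (amplitude threshold at half the 98th percentile, then a
   refractory pass at 0.6× the median peak spacing that removes
   diastolic-shoulder false positives on slow-rising pulses). Each
   beat boundary is the PPG minimum found by searching backward from
   an upstroke over 0.45× the median beat spacing — a window short
   enough to avoid the band-pass undershoot after the previous
   systolic peak. Inter-boundary intervals outside 30–180 bpm are
   discarded. Sub-sample upstroke positions ("anchors", 3-point
   parabolic refinement) are retained for the noise estimator.
4. **Landmarks and features.** Per beat: baseline-corrected pulse
   height S (maximum above the straight line joining the bounding
   minima); VPG FWHM by linear interpolation of the half-maximum
   crossings around the parabola-refined peak; APG a-wave (global APG
   maximum between beat onset and the PPG maximum), b (first trough
   after a), then c/d/e as alternating extrema within the first 80% of
   the beat — late-diastolic extrema are never assigned. All peak
   times are parabola-refined so delays below one sample period remain
   resolvable. Features: S, 1/S, a, a/S, FWHM_VPG, 1/FWHM_VPG, ab
   time, 1/ab, normalized a−b and a−d (APG scaled so the a-wave is 1)
   and their ratio.
5. **Channel delay.** Each NIR a-peak is paired with the nearest green
   a-peak within ±0.3 s (ties to the earlier green peak; 0.3 s is less
   than half the shortest plausible beat period). The per-beat delay is
   t(green a) − t(NIR a); the record summary is the median (the delay
   varies beat to beat, and the median resists outliers; the mean is
   available by configuration).
6. **Record aggregation.** Per-feature median over valid beats
   (configurable to mean); beats missing a landmark contribute to the
   features they do support.

## Quality control

SNR is the pulse height S divided by the RMS of what remains after
removing the repeating pulse component. The pulse component is the
ensemble-average beat template; the residual is computed on the raw
channel after a 0.5 Hz zero-phase high-pass — not the 0.5–20 Hz
analysis band-pass — so that broadband (including in-band motion)
noise is counted at its full RMS.

Template alignment is the crux of this estimator: with ±3% beat-period
variability, naive boundary-to-boundary normalization leaks waveform
into the residual. The implementation therefore (i) reconstructs beat
onsets from the sub-sample upstroke anchors by solving
a_k = (1−γ)o_k + γo_{k+1}, choosing the anchor phase γ by minimizing
the residual itself; (ii) refines each beat by one Gauss–Newton time
shift against the template gradient; and (iii) removes a per-beat
linear trend from the residual (heart-rate variability modulates the
per-beat DC level at beat-rate sidebands the high-pass cannot remove).
Each of these corrections has ≤2 degrees of freedom per ~10³-sample
beat and therefore cannot absorb broadband noise; on simulated records
the estimator recovers injected white-noise σ within 2% when beats
repeat exactly and within ~1.5 a.u. of alignment floor under 3% HRV.
Beats within 3 s of the record edges are excluded (zero-phase
transients at a 0.5 Hz corner), with the margin shrunk adaptively on
short records.

Records are excluded when any analyzed channel (green and NIR by
default) has SNR strictly below 200, when wrist systolic pressure is
missing, or when no feature could be computed; SNR exactly 200 is
kept. Exclusion is data, not an error.

## The simulator

Purpose: every pipeline stage must be testable against known ground
truth, because no raw recordings are published. The generator makes a
dual-channel record whose true steepness, delay and noise are known.

* **Beat model.** One beat is the sum of a systolic and a diastolic
  Gaussian (amplitude ratio 0.35, centers at 22% and 55% of the
  cycle). This is deliberately the simplest shape with a full a–e APG
  sequence; it makes no claim to pulse-decomposition physics. One
  consequence is accepted: for a symmetric systolic Gaussian the APG
  trough at the peak is ~2.2× the foot maximum, so simulated
  normalized a−b is ~3 where clinical APGs give 1–2; the steepness and
  delay features under study are unaffected.
* **Phase-warped train.** The record is a warped periodic waveform:
  each beat span carries the periodized one-cycle shape stretched
  self-similarly by its own period (period jitter: truncated normal,
  CV 3% by default). Beat morphology is thus exactly self-similar
  under heart-rate variability — the idealization the QC template
  assumes — and the beat-rate modulation of mean level that real HRV
  produces is present.
* **Channels and delay.** The NIR channel is the train itself; the
  green channel is the same train evaluated at t − d(t), where the
  delay field d(t) interpolates per-beat delay values (mean = the
  record's true delay; per-beat jitter, default SD 3 ms, reflecting
  the beat-to-beat variability reported for real measurements)
  linearly between onsets. Evaluating the continuous waveform at
  shifted times gives genuine sub-sample delays with no seams. The
  per-beat ground-truth delay is the field at the early-systolic
  reference point (12% of the cycle), where the a-wave lives.
* **Calibration.** The map from systolic width σ_s to measured
  1/FWHM_VPG is inverted by Brent root-finding, where "measured" means
  a noiseless beat train passed through the full default pipeline
  (filter, smoothed derivatives, segmentation, FWHM). Calibration
  therefore already accounts for the width added by the 20 Hz corner
  and the 50 ms smoothing, and recovery of the target is unbiased by
  construction of the generator, not by tuning. A cached 20-point
  σ↔1/FWHM curve (per heart rate/sampling rate/filter setting,
  trimmed to its strictly monotone branch — beyond it adjacent beats
  merge) brackets the root so per-record calibration costs a few
  evaluations. Achievable range at 65 bpm/1 kHz: ≈3.7–32 1/s; slower
  heart rates extend the lower end.
* **Presets.** Per-record parameters are log-normal: positive,
  right-skewed quantities. Locations match the reported group means
  exactly (arithmetic-mean parameterization); log-SDs are set so the
  reported group minima/maxima fall at the extreme quantiles of a
  cohort of the reported size: 0.20 for 1/FWHM_VPG (both groups), 0.60
  (diabetes) and 0.45 (control) for delay. Wrist SBP is normal
  (135±15 diabetes, 118±12 control — the report states only that
  diabetic pressures "tended to be higher"). Cohort draws are
  stratified (one draw per equiprobable quantile stratum, shuffled) so
  that small cohorts are representative of the preset distribution;
  i.i.d. draws are available (`stratified=False`). Heart rate is held
  at 65 bpm across records: none of the features under study depends
  on it, and a fixed rate lets one calibration curve serve a cohort.
* **Defaults.** 30 s records at 1000 Hz (sub-10-ms delays need ≤1 ms
  samples with interpolation), amplitude 1000 a.u. on a 2000 a.u.
  baseline, white sensor noise σ=2 (SNR ≈ 300–500, comfortably above
  the 200 threshold), sinusoidal drift of 10 a.u. over 30 s, motion
  artifacts (tapered random-walk bursts) off except in QC tests.

## What the simulation does and does not show

Passing the cohort tests shows that the pipeline recovers known
steepness and delay without bias at realistic SNR, beat-rate
variability and beat-to-beat delay jitter, and that the published
group separation follows from the published group distributions at the
published sample sizes. It does not validate the waveform model
against real tissue optics (no photon transport, no absorption
spectra — wavelength labels are semantic), does not model
within-subject correlation of repeated measurements (records are
independent; the real cohorts had up to 8 records per subject), and
does not exercise pathological morphologies beyond the two-Gaussian
family.

## Numerical choices and degenerate inputs

Sub-sample extremum timing: 3-point parabolic interpolation, falling
back to the sample at array edges or degenerate curvature. FWHM
half-level: half the parabola-refined peak; crossings by linear
interpolation; a beat whose half level is not crossed on both sides is
invalid for that feature. Division by a non-positive denominator
suppresses only the dependent feature. Constant or non-pulsatile
signals yield an empty flagged beat index, never an exception. Zero
estimated noise reports SNR at a 10⁶ cap with a flag. Records shorter
than 2 s, with non-monotone time, or with >1% sampling jitter are
rejected at load (no resampling).

## Problem sizes used in the test suite

Cohort-mean recovery runs both presets at the reported sizes (50 and
21 records) with full-length 30 s records at 1000 Hz. The
direction/significance Monte-Carlo runs 100 replicates of 50-vs-21
cohorts with 8 s records — the comparison operates on record-level
medians, which stabilize within a few beats, so shorter records leave
the test's statistical content unchanged while keeping the suite
fast. Parameter-recovery uses a 4×4 grid over 1/FWHM ∈ [3, 15] 1/s ×
delay ∈ [0.003, 0.073] s at 50 bpm (the widest upstrokes need the
longer cycle).

## Known limitations

* The ensemble-template noise floor (~1–2 a.u. under 3% HRV) adds to
  injected noise in quadrature; SNR estimates on very clean records
  are therefore slightly conservative.
* γ-registration assumes one upstroke phase per record; morphology
  changes within a record (e.g. the pressure-press experiment) would
  inflate the noise estimate — conservative, but worth knowing.
* `select_height_ordered` implements only the two objective criteria
  (all three postures present, strictly descending pressure); the subjective
  minimal-overlap screening used to de-clutter plots is not
  implemented.
* The delay pairing assumes both channels see the same beat sequence;
  severe dropouts on one channel reduce the pair count rather than
  failing the record.
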