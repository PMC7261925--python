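# Methods

This note records the models implemented in `fnirskit`, the parameters
that matter, and the design choices made where more than one reasonable
option existed.

## Beer–Lambert conversion

Continuous-wave NIRS measures light attenuation only, so absolute
chromophore concentrations are not identifiable; the pipeline works with
concentration *changes*.  For each channel and wavelength the attenuation
change is ΔA[n] = log₁₀(I₀ / I[n]).  The reference intensity I₀ defaults
to the temporal mean of the trace over the run: CW-NIRS fixes no absolute
reference instant, and the mean keeps ΔA centered so the later baseline
high-pass sees no large step.  An explicit per-channel baseline can be
supplied instead (the synthetic generator's ground truth does this to
verify exact inversion).  Constant scattering loss cancels in the
differential form and is not modelled.

The two-wavelength system is solved per sample with a single 2×2 matrix
inverse.  The extinction coefficients are **configuration, not physics
baked in**: the defaults (in 1/(mM·mm), rows 760/850 nm, columns Hb/HbO₂:
0.154852, 0.058600; 0.069132, 0.105800) come from the standard compiled
hemoglobin absorption spectra used across CW-NIRS software, and the
differential path length factors default to the adult-head values 7.25
(760 nm) and 6.38 (850 nm).  Source–detector distance defaults to 30 mm
(~3 cm optode spacing).  All concentration tests use a forward/backward
round trip as the oracle, so correctness does not depend on the particular
constants chosen.

## Filter bank

* **Power-line notch** — second-order IIR notch at 50 Hz with a −3 dB
  bandwidth of 1.43 Hz, applied only to ECG and respiration at their
  native rates (their Nyquist is far above 50 Hz; the fNIRS, BP and HR
  devices remove mains interference internally).  Rates ≤ 100 Hz are
  rejected.
* **Baseline high-pass** — 6th-order Butterworth, passband edge 0.005 Hz.
* **Optional low-pass** — 8th-order Butterworth with a user-selected
  cutoff, for technical artifacts above the band of interest.

Edge convention: "cutoff" means the **passband edge**, and each
Butterworth is designed so the magnitude drop at that edge equals its
quoted passband ripple — 1 dB for the high-pass, 3 dB for the low-pass
(for a Butterworth the 3 dB ripple coincides with the classical −3 dB
corner to ~0.03 %).  The −3 dB corner is therefore placed at
f_c = f_edge · (10^(ripple/10) − 1)^(1/2n) (inverted for the high-pass).
A Butterworth's monotone stopband is not a free design parameter once the
order is fixed; the quoted 30 dB stopband attenuation is carried as
metadata and verified to be reached (below ~0.003 Hz for the high-pass,
past ~2.4× the cutoff for the low-pass).

Filters are stored and applied as second-order sections (the 0.005 Hz
edge at a 3.91 Hz rate puts poles extremely close to the unit circle;
transfer-function polynomials would be numerically fragile).  Application
is **causal single-pass**; design conformance is measured on the transfer
function, not on filtered output.  Signals shorter than 3× the filter
order are rejected.

## Stream alignment

Physiological streams (200/256 Hz) are brought to the fNIRS timeline by a
zero-phase 4th-order Butterworth low-pass at 0.45× the fNIRS rate followed
by linear interpolation onto the fNIRS timestamps.  Interpolation onto the
timestamp grid (rather than polyphase resampling) was chosen because XDF
streams carry irregular per-sample timestamps and the rate ratio to
3.91 Hz is not a small rational; the anti-alias filter does the real work,
and the interpolation error at a 256→3.91 Hz ratio is negligible (the
test suite bounds it at <1 % RMS for an in-band sine and verifies mean
preservation).  Markers map to the nearest fNIRS sample **at or after**
their timestamp, so an epoch never starts before its event.  Sample
indices are 0-based and time windows half-open [start, end).

## Physiological features and regressors

Beat detection on the continuous BP trace picks systolic peaks as local
maxima with a 0.33 s refractory interval (≤180 bpm) and a prominence of a
quarter of the trace's range; each diastolic value is the minimum in the
preceding inter-beat interval.  R-peak detection band-passes the ECG to
5–30 Hz, optionally flips polarity when the dominant deflection is
negative, squares the positive part and applies the same refractory
peak-picking with an adaptive threshold (20 % of the 99.5th percentile of
the energy).  Flat traces degrade to empty results with a warning, not an
error.  Elevated blood pressure is annotated when mean systolic exceeds
140 mm Hg or mean diastolic exceeds 100 mm Hg (strict inequalities, as
printed).

Each artifact's reference regressor is its source trace band-passed to the
artifact's correction band with a 4th-order zero-phase Butterworth and
mean-removed.  Zero-phase filtering keeps regressor lags interpretable;
any residual lag is absorbed by the FIR taps of the transfer-function
model.  Default sources: Mayer waves from the diastolic beat series
(selectable among diastolic BP / systolic BP / heart rate, falling back to
heart rate when BP is absent), respiration from the belt trace, and the
cardiac artifact from the pulsatile BP trace — its fundamental sits at the
heart rate, whereas the beat-wise rate-in-bpm trace has no spectral power
there.

## Artifact model and correction

Default spectral search windows: Mayer 0.07–0.13 Hz, respiration
0.2–0.4 Hz, cardiac 1.0–1.5 Hz.  The correction band defaults to the
search window widened by ±0.02 Hz and is user-overridable.  Artifact peaks
are located as the maximum of a Welch spectrum (Hann window, 120 s
segments or the full trace if shorter, 50 % overlap, reported in dB)
inside the search window; a peak less than 3 dB above the window's median
counts as not found, and exact ties resolve to the lower frequency.

* **CAR** subtracts the cross-channel mean at every sample, separately for
  the oxy and deoxy channel sets; it needs ≥2 channels and leaves a
  cross-channel mean that is exactly zero.
* **SOBI-ICA** whitens the demeaned channel block, forms symmetrized
  covariance matrices at lags 1…min(100, samples/3) and jointly
  diagonalizes them by iterative Givens rotations (convergence when all
  rotation sines fall below 1e-8, at most 200 sweeps).  A rank-deficient
  channel covariance raises an error advising channel exclusion.  A
  component is attributed to an artifact when more than half its spectral
  power lies in some correction band **or** its absolute correlation with
  that artifact's regressor exceeds 0.6 — the selection rule is this
  package's own; reconstruction zeroes the selected source rows.
  Oxy and deoxy channel sets are decomposed and corrected independently.
* **Transfer-function models** fit X[n] = Σ_{u=0..m} gᵤ·Y[n−u] + N[n] per
  channel by least squares over the samples where all lags exist, and keep
  the residual.  Default order m = 8 (~2 s of lags at 3.91 Hz),
  configurable.  Lagged copies of a narrow-band regressor are nearly
  collinear, so the solve truncates singular values below 1e-6 of the
  largest; this keeps the taps bounded without visibly changing the fit.
  The first m output samples use zero-padded lags.  Artifacts are removed
  sequentially (Mayer, then respiration, then cardiac) on the running
  residual, per chromophore.

"Uncorrected" is the identity on the concentration block.

## Epoching and averaging

An epoch spans round(pre·rate) samples before its marker to
round((task+post)·rate) samples after it; with the reference 5/12/8 s
block design at 3.91 Hz that is 20 + 78 = 98 samples, with t = 0 at task
onset.  Epochs that would cross the recording edge are dropped with a
warning; a condition with no matching markers is an error; a mismatch
between expected and observed trial counts warns and proceeds with the
observed markers.  Trial averages use only non-excluded trials and
channels; exclusion indices are 1-based in the configuration (users count
from one) and 0-based internally.  The standard deviation uses the n−1
denominator; a single kept trial reports SD 0 with a warning.  An optional
per-trial baseline (subtracting each trial's pre-task mean) is available
and off by default.  Faulty-optode channels can be replaced by the
element-wise mean of named neighbor channels.  Grand averages and ROI
traces are plain element-wise means (over subjects and over member
channels); an ROI referencing an excluded channel is an error.

## Montages, maps and outputs

Channel positions live on the unit disc and affect visualization only,
never statistics; the shipped montage places channels on a regular grid
scaled to radius 0.9 and can be replaced.  Topographic maps average each
channel inside configured time windows (default −5–0, 0–7, 7–14, 14–20 s),
clip to the configured concentration range, and use linear scattered-data
interpolation masked outside the channel convex hull.  Tables are CSV at
full float precision (12 significant digits), with an `.xlsx` copy when
openpyxl is available; file names carry the subject/task/condition prefix
and correction-method suffix, under `study/subject/run/condition`.  The
run log records every step, parameter and warning in order.

## Synthetic generator

The generator emulates the supported acquisition stack: fNIRS at 3.91 Hz
with 760/850 nm intensities, ECG and respiration at 256 Hz, BP and HR at
200 Hz, and an integer marker stream.  The clean oxy response is a
single-gamma kernel (shape 6, time-to-peak 6 s — inside the 5–10 s
hemodynamic timescale — with a 15 % undershoot) convolved with the task
boxcar and scaled to a 1e-3 mM·mm peak; the deoxy response is −0.3× the
oxy response (typical antiphase behavior).  Systemic oscillations at
0.10 / 0.30 / 1.20 Hz with ±10 % slow frequency wander are shared across
channels with per-channel gains (0.8–1.2×) at amplitudes 4e-4 / 2e-4 /
2e-4 mM·mm, plus white noise of SD 1e-4.  Intensities follow the exact
Beer–Lambert forward model around per-channel baselines, so conversion is
verifiable to numerical precision.  Crucially, the biosignals are
phase-locked to the same oscillators: BP carries a 3 mm Hg Mayer
modulation and beats at the cardiac oscillator's phase crossings (120/80
mm Hg, ~72 bpm), the respiration belt follows the respiratory oscillator,
and the HR trace carries a 2 bpm Mayer modulation — so transfer-function
correction has a truthful reference.  Everything is deterministic under
the seed, to the byte on disk.

What it does **not** emulate: motion artifacts, optode-coupling drift and
spiking, spatially structured (non-common-mode) systemic activity,
scattering changes, heteroscedastic detector noise, and realistic ECG
morphology variation.  Passing tests therefore demonstrate correctness of
the algorithms under the stated signal model, not robustness to every
failure mode of real recordings.

Default problem sizes (10 trials × 25 s + lead-in/out ≈ 290 s, 8
channels) keep a full simulated analysis around a second while leaving
>10 artifact cycles per band for spectral estimates; tests reuse one
session-scoped recording where possible.

## Known limitations

* Correction quality in a band is floor-limited by in-band measurement
  noise: regression rightly removes only the reference-coherent component,
  so the measurable band-power reduction for the cardiac band saturates
  near the noise floor (~87 % under the generator defaults, with the
  coherent artifact itself removed to ~1 % residual).
* The XDF codec covers the chunk types and channel formats this pipeline
  uses and does not apply clock-offset correction; files written by other
  recorders with clock drift may need external preprocessing.
* The trial-average peak is referenced to the run mean unless per-trial
  baseline subtraction is enabled; with densely packed trials the pre-task
  interval contains the previous trial's tail, biasing baseline slightly
  low.
* No inferential statistics (GLM, t-maps): tables are exported for
  downstream analysis.
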