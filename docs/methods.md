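# Methods

This note documents the models and procedures implemented in
`betaburst`, the parameter choices and their rationale, what the
synthetic data do and do not emulate, and the numerical decisions a
maintainer should know about.

## Real-time detection pipeline

### Filter bank

Each channel is a windowed-sinc FIR bandpass: the ideal response
(difference of two lowpass sincs at Fc ± 0.5 Hz) truncated to N + 1 =
257 taps, multiplied by a triangular (Bartlett) window, and divided by
|H(Fc)| so the gain at the passband centre is exactly 1.  This equals
the classic `fir1`-style design with a triangular window and passband
scaling (the test suite asserts coefficient-level agreement with
`scipy.signal.firwin`).  Defaults: order N = 256, centres 1–32 Hz in
1 Hz steps, Fs = 976.5625 Hz exactly (the acquisition hardware's
"~1 kHz" rate).

Two width conventions exist for "full width at half magnitude".  For
this design the **power response** |H(f)|² crosses half its peak
4.89 Hz apart (the −3 dB bandwidth, ~5 Hz); the |H(f)| = 0.5 crossings
are 6.8 Hz apart.  `fwhm()` measures the half-maximum width of the
power response, which is the convention under which the design is
quoted as a 5 Hz-wide filter; the crossing search runs bisection on
the continuous response with a 1e-4 Hz tolerance (grid-free and
deterministic).

The symmetric taps make the group delay exactly N/2 = 128 samples at
every frequency — verified empirically from the phase slope to ±0.01
samples.  In milliseconds this is 131.07 ms at the physical rate; under
the nominal one-sample-per-millisecond convention it is quoted as
128 ms, and `latency_ms()` defaults to that nominal convention plus a
configurable 2 ms computation budget (130 ms total).  Samples are the
ground truth; the millisecond figure is nominal.

### Streaming core

Filtering is causal FIR convolution.  The streaming implementation
carries the last N input samples across chunk boundaries and computes
every output sample as the same ordered dot product with the taps, so
chunked and whole-signal processing agree **bit for bit** (recursive
filter-state updates, e.g. `lfilter` with `zi`, differ at the last ulp
across chunkings and were deliberately avoided).

Turning points are detected by three-sample comparison on each
filtered channel, skipping plateaus; on a plateau the first sample is
the extremum (earliest causal choice, deterministic), and the event is
emitted at the first sample at which the reversal is observable.  Peaks
and troughs strictly alternate by construction.  The squared extremal
amplitude is latched from the emission sample until the next emission;
the track is 0 before the first extremum (nothing latched yet).  On a
pure tone of amplitude A the track converges to A² (unity gain at the
centre) with updates every half period.

Phase is a sawtooth of slope 2πf reset to 0 after peaks and π after
troughs, delayed by δ(f) = ⌈d/T⌉·T − d (d = physical group delay in
seconds, T = 1/f), which schedules the reset on the next extremum of
the *input* signal.  Resets reference peaks, i.e. cosine phase; on a
pure tone the circular mean absolute error is < 0.05 rad in steady
state.  The per-sample phase/power representations on the raw clock are
an implementation choice — whether the original hardware resampled
between extrema is not observable from outside.

### Artifact rejection and threshold

Artifacts are amplitude excursions of a 2nd-order Butterworth 2–250 Hz
bandpassed copy of the raw trace (12 dB/octave per edge) beyond 500 µV;
flagged samples are dilated by ±0.5 s.  Note that a *single-sample*
impulse loses most of its amplitude in that prefilter — realistic
artifacts (tens of ms) are what the threshold is meant for, and the
tests use a 20 ms deflection as the exemplar.

The per-channel threshold is the 98th percentile (linear interpolation
between order statistics, identical to a sort-based computation) of a
FIFO holding the most recent 15 s worth of artifact-free power samples,
recomputed once per second of wall-clock input.  Skipping masked
samples when appending to the FIFO *is* the back-fill rule: a masked
stretch leaves the older clean samples in the window, so the percentile
always rests on a full 15 s of clean data.  History granularity is one
value per raw sample.  Until the FIFO has filled once, the threshold is
"not ready" (NaN) and nothing can flag — operationally the first 15 s
of a session are covered by priming rewards.

On stationary noise the long-run fraction of samples above threshold
converges to ~2%, and planting a huge (masked) artifact moves the
thresholds by well under 1%.

### Burst rule and rewards

flag(f, t) = [P(f,t) > P(f−1,t)] ∧ [P(f,t) > P(f+1,t)] ∧
[P(f,t) > threshold(f)], with strict inequalities (ties lose), and
channels 1 and 32 never flag (missing neighbour).  Maximal runs of
flags per channel become events; events in the target band lasting
≥ 70 ms are reward-eligible.  Duration gating is per single channel by
default; `band_union=True` instead gates on the OR of the in-band flags,
so a burst drifting between adjacent channels still accumulates
duration (which behaviour the original system had is not documented;
both are provided).  Rewards: 5 priming rewards every 3 s in the first
15 s; then one reward per eligible event, decided at onset + 70 ms +
latency (default 2 ms), suppressed during delivery (volume/rate,
default 50 µl at 50 µl/s) and for 1 s after any reward, and inside
artifact-dilated spans.  Sham mode replays a recorded schedule exactly
and ignores the signal.

## Surrogate generator

A synthetic recording is the sum of (i) Gaussian-windowed sinusoids
a·sin(2πf(t−t₀))·exp(−(t−t₀)²/2σ²) ("bursts", zero phase at centre),
(ii) pink noise made by shaping seeded white Gaussian noise to a 1/√f
amplitude spectrum (PSD slope −1) and rescaling to an exact target RMS,
and (iii) white Gaussian noise with target RMS.  Defaults: pink RMS
1.5, white RMS 0.3, burst amplitude 1 (sinusoid peak), the adjacent
20/21 Hz pair configuration.  Everything derives from one seed via
`numpy` seed sequences and is reproducible bit for bit.

Burst envelope widths: the generic default is σ = 0.04 s (envelope
FWHM ≈ 94 ms, matching the short-burst regime and the 70 ms reward
gate).  The *resolution-study* configuration uses σ = 0.1 s: a Gaussian
burst has spectral width σ_f = 1/(2πσ_t), so at σ_t = 0.04 s the
spectrum is ~4 Hz wide and asking whether such a burst is at 20 or
21 Hz is ill-posed regardless of noise — the time–frequency uncertainty
principle requires σ_t ≳ 0.1 s (σ_f ≲ 1.6 Hz) before 1 Hz assignment
is meaningful.  Each repetition is a fresh 10 s noise realisation with
one pair (centres at 3 s and 7 s).

What the surrogate does **not** emulate: 1/f "knee" structure and
non-stationarity of real LFP, movement and chewing artifacts,
volume-conducted broadband transients, electrode drift, or any
behavioural correlation between bursts.  Passing the recovery tests
therefore shows the detector's signal-processing behaviour under
calibrated SNR, not performance on any particular animal's recording.

## Offline analysis

The offline TFR is a complex Morlet convolution, σ_t = cycles/(2πf)
(7 cycles conventionally; 3 cycles for the short-delay online-matched
variant), kernels truncated at ±4σ_t and scaled so a unit-amplitude
tone yields power 1.  Bursts are strict 8-neighbourhood local maxima of
the un-normalised TFR above the per-frequency 98th percentile of the
whole recording (plateau maxima take the earliest time, then the lowest
frequency).  Per burst: span = contiguous supra-threshold frequency
extent at peak time; duration = contiguous supra-threshold time extent
at peak frequency; inter-burst interval = peak-time difference to the
previous burst; power as fraction of the per-frequency median (> 1 by
construction).  The percentile is per-frequency, not global — a global
cut would be dominated by the 1/f spectrum's lowest channels.

Time-locked averaging bandpasses the raw trace 15–30 Hz (zero-phase),
finds the last local minimum before each event (within 300 ms), and
averages raw windows centred on those troughs, with a t-distribution
95% band.  Aligning phase-heterogeneous bursts this way manufactures
the appearance of a sustained oscillation in the average — the package
exposes `align_to_trough=False` (event-centred, incoherent) as the
control, under which the average shrinks as 1/√n.

Session statistics: the per-session percent power change averages, over
the n = 6 targeted frequencies, the session-mean power normalised to
session 1 (session 1 ≡ 0; invariant to global rescaling; artifact
epochs are excluded by the caller).  The training effect is
(P̄₉,pre − P̄₉,post) − (P̄₁,pre − P̄₁,post) per frequency, pre/post
being mean TFR power 200 ms before/after reward; group testing over
frequencies is a thin t-test + Bonferroni layer on top.

## Method comparison

Four decompositions share one grid (12–32 Hz, sample-clock steps):
Morlet 7/3 cycles; sliding Hanning-window DFT power with 250 ms
(offline) / 150 ms (online) windows; "variation" = power of a
narrow-band filtered copy over 150 ms (offline) / half-period (online)
sliding windows; and the filter-extrema pipeline itself.  Notes:

* The variation filter is a Kaiser-window FIR (1 Hz passband, 12 dB
  stopband, 2.5 Hz transition).  12 dB is below the 21 dB knee of the
  Kaiser design rule, so the optimal shape parameter is β = 0; the
  original routine's internals are not public and this stands in as a
  documented substitution.
* The variation estimate is the in-window *mean square* of the
  (zero-mean, narrow-band) filtered signal.  A literal mean-subtracted
  variance is phase-unstable for half-period windows (the window mean
  of a sinusoid oscillates with phase) and would make even a pure tone
  non-stationary, which cannot be the intended estimator.
* All methods are evaluated time-aligned: centred windows for
  wavelet/FFT/variation, and the filter-extrema track shifted back by
  its known group delay.  Absolute scale is irrelevant because the SSE
  metric divides each method by its own median over all trials.

SSE(m, n) = Σ_t Σ_f (P(m,n,t,f)/P₅₀(m) − P(w,n,t,f)/P₅₀(w))² with w the
7-cycle wavelet reference and P₅₀ the median over all trials of the
method.  The default benchmark is one 303 s trace at 1000 Hz (so one
sample = 1 ms exactly) with 100 planted 20 Hz bursts (σ = 0.04,
amplitude 1) every 3 s in the default noise; trials are the planted
times ± 0.5 s, with the rest of the continuous trace serving as
padding.  On this benchmark the online filter-extrema SSE distribution
is stochastically far below online FFT and online variation (one-sided
rank tests, p < 1e-13): the 150 ms Hanning window blurs frequency
(~10 Hz main-lobe FWHM) and the half-period variance is noisy, while
the narrow filter bank keeps 5 Hz selectivity at half-period time
resolution.

## Resolution study

Each of 50 repetitions synthesises a fresh 20/21 Hz pair realisation,
runs the filter-extrema detector with a *static* per-channel 98th
percentile over the 10 s trace (the 15 s dynamic window cannot fill on
a 10 s simulation; a static percentile is the faithful offline analogue
of the threshold), and records the detected frequency of each planted
burst.  Matching is covering-first: among flagged events (12–32 Hz
analysis band) whose supra-threshold run covers the delay-compensated
planted centre, the one with the largest power *relative to its own
channel threshold* wins — absolute power would be dominated by the 1/f
noise floor of the lowest channels; if no event covers the centre, the
nearest peak-power time within ±0.15 s (±1.5 envelope σ) is used.

The test statistic is the Wilcoxon rank-sum z (normal approximation,
midranks, tie-corrected variance) between first- and second-burst
frequency samples; the p-value is the fraction of 10,000 label
permutations (pooled detections, group sizes preserved) whose |z|
reaches the observed |z|.  At the default conditions the median
absolute frequency error is 1.0 Hz and p < 0.05; because the design is
a single 50-repetition draw, the p-value itself fluctuates across
generator seeds (a minority of seeds land between 0.05 and ~0.17), which
is inherent sampling variability of the study design, not a detector
property.  The packaged test runs the canonical default seed.

## Numerical and interface choices

* Sample indexing is 0-based; exported intervals are half-open
  [onset, offset); exported times carry 6 decimals; TSV for tables,
  JSON for reports, YAML for run configuration (lossless round-trip).
* Percentiles everywhere are linear interpolation between order
  statistics.
* `run_session` is fully deterministic: same configuration + same
  input ⇒ byte-identical output files.
* Degenerate inputs are rejected loudly (empty streams, streams shorter
  than the filter order, non-finite samples, odd filter orders, centre
  frequencies within half a passband of 0 or Nyquist, unsorted event
  lists, irregular CSV time axes — the first offending row is named).
* EDF input is read via `mne` (first channel, header rate, volts
  converted to µV); CSV is `time_s,amplitude_uv`.  EDF export is out of
  scope.

## Known limitations

* The emulation is sample-synchronous and offline; it reproduces the
  algorithmic behaviour and latencies of a real-time system but gives
  no scheduling guarantees, and hardware I/O (TTL, pumps, audio) is
  represented as log events only.
* The artifact stimulus (white-noise punishment) and reward hardware
  behaviour are not modelled beyond their timing consequences.
* Burst statistics from the offline characterization depend on the
  98th-percentile definition; with a constant TFR nothing exceeds its
  own percentile and no bursts are reported, which is the intended
  degenerate behaviour.
* The dynamic threshold needs a full 15 s of clean history before the
  detector can fire; short recordings should use the static-percentile
  pathway as in the resolution study.
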