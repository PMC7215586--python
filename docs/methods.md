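# Methods

This note records the scientific model behind each component, the
parameters that matter, and the numerical and design choices made where
the behavior was genuinely open.

## Time synchronization

The signal and video timelines are related by

    video(t) = rate_factor · (t − video_offset) + Σ { skip_j : t_j ≤ t }

* `video_offset` (s) — signal-timeline time of video frame 0. A camera
  that started 2.51 s before signal acquisition has offset −2.51 s.
* `rate_factor` (dimensionless, > 0, default 1) — corrected video clock
  = recorded video clock × rate_factor. The correction is applied about
  video time 0, **before** jumps are added; the composition order is
  fixed by this contract since either order defines a usable map.
* `jumps` — (signal_time, skip ≥ 0) pairs, strictly increasing. Declaring
  jumps in the signal timeline keeps the forward map total and strictly
  increasing, hence invertible; video times falling inside a skipped
  span invert to the jump's signal time (a deliberate boundary
  convention — those frames have no corresponding signal moment).

Frame lookup is `floor(video(t) · fps)` clamped at 0: the displayed
frame is the last frame at or before the cursor.

Counter-based offset estimation models the lab protocol of filming a
digital counter that increments at a fixed rate (10 Hz here) while its
pulses are recorded with the signals: if the counter shows `count`
(1-indexed) at video time `v`, then
`video_offset = pulse_times[count] − v`. Recovery on synthetic data is
exact to float precision (≪ 1 ns).

The strict-monotonicity property holds mathematically for all valid
parameters; in floating point it is guaranteed only for time differences
above ~1e-9 s at second-scale magnitudes, which is the resolution the
round-trip tolerance also uses.

## Epoch model and algebra

Epochs are half-open `[start, end)`: a peak at exactly `end` is outside.
Half-openness makes containment unambiguous when epochs tile a record.

* `merge_adjacent(epochs, tol)` coalesces same-label epochs whose gap
  (possibly negative, i.e. overlap) is ≤ tol. Implemented as a sorted
  sweep per label; this equals the transitive-closure fixpoint because
  intervals live on a line. Order-insensitive and idempotent.
* `fill_gaps(epochs)` extends each epoch's end to its successor's start.
  Extending the **earlier** epoch (rather than splitting gaps at their
  midpoint) is deterministic, order-free, idempotent, and conserves the
  overall span. Overlapping input is rejected.

## Filtering

Butterworth IIR of the configured order (default 2), applied
forward–backward (`sosfiltfilt`) for zero phase: spike peak *times* are
preserved, which peak detection depends on, at the cost of squaring the
magnitude response (an order-2 lowpass behaves like order 4 in
amplitude). Cutoffs must lie below Nyquist; both-cutoff specs become a
bandpass. Length, sampling rate and timestamps are unchanged.

## Peak detection

Strict-left/non-strict-right local extremum rule
(`x[i−1] < x[i] ≥ x[i+1]`, mirrored for negative windows): a plateau of
equal samples counts once, at its first sample — deterministic on
digitized data, where exact ties do occur. First and last samples are
never peaks. The amplitude window may not straddle zero (enforced at
configuration time too): a window containing zero would fire on noise
around baseline and has no physiological reading in terms of a unit's
spike height. The epoch constraint keeps peaks in the union of all
half-open epochs bearing the label, matching annotations in which one
label marks several activity periods.

## Burst detection

Instantaneous frequency is the reciprocal ISI. Scanning left to right:
a burst opens at spike *i* (when none is open) iff `f_i ≥ f_init`,
absorbs spike *j+1* while `f_j ≥ f_term`, and closes at the first spike
whose following ISI fails `f_term`. Choices fixed by this contract:

* a burst spans **first to last member spike** and needs ≥ 2 spikes
  (frequency is undefined for one spike; lone slow spikes flanking a
  burst are excluded);
* a closed burst may not reopen at its closing spike — scanning resumes
  at the next ISI — so bursts are disjoint and ordered;
* `f_init ≥ f_term > 0` (opening implies continuing).

The scanner is verified against an independent exhaustive oracle
(enumerate all contiguous subsequences that open at `f_init`, continue
at `f_term`, are maximal under right-extension, selected greedily left
to right) over **every** spike train of ≤ 6 spikes on a 0.05 s grid
spanning [0, 1] s — 82,160 trains — under several threshold pairs.

## RAUC

Baseline (none, mean, or median) is computed over the **whole** channel,
not per bin, so bin values remain comparable; then full-wave
rectification and integration per bin as sample sum × 1/fs
(units·seconds). The trailing incomplete bin is dropped. The per-bin
**integral** (not the bin mean) is reported; dividing by `bin_duration`
converts between the two. Bin width in samples is `round(bin_duration ·
fs)`. Exactness caveat: "constant signal with mean baseline gives zero"
holds exactly when the mean is computed without rounding (e.g. dyadic
constants); otherwise bins are zero to ~1e-16 relative.

## Synthetic data generator

The generator emulates the shape of an extracellular feeding-behavior
recording: one nerve channel (`BN2`) with spike templates from a few
units summed into Gaussian noise, one slow clean force-like channel
(`Force`, a 0.25 Hz sine) for filtering/RAUC, epochs labeling the active
periods, counter pulses from signal time 0, and a configuration whose
discriminators and burst detectors recover the truth.

Default study conditions: 5000 Hz sampling, 10 Hz counter, 30 fps video
with offset −2.51 s, 60 s duration, three units with amplitudes 20 / 80
/ 320 µV and noise SD 2 µV (SNR 10 for the smallest unit). Amplitudes
are kept a factor > 3 apart so the emitted `[0.5 A, 1.5 A]` windows are
disjoint, and ≥ 4 × noise SD apart so classes cannot blur; violating
either is a generation-time error, because ambiguous ground truth is
useless.

Spike trains are pure bursts: per burst, 5–10 spikes with ISIs jittered
uniformly ±10 % around `1/within_burst_rate`; burst onsets are drawn
uniformly and rejection-sampled so bursts never overlap **across units
either** (waveform superposition would make ground-truth amplitudes
ambiguous). `burst_rate` is the reciprocal of the minimum gap between a
unit's bursts. Emitted thresholds `f_init = within_burst_rate/2`,
`f_term = within_burst_rate/4` bracket the within-burst frequencies
(≥ 0.9 × rate) from above the inter-burst frequencies (≤ min(burst_rate,
within_burst_rate/5)), which makes the generator's bookkeeping and
`detect_bursts` provably agree on the true spike times.

Templates (width 1 ms, peak normalized to the unit amplitude, spike time
= peak sample): `biphasic` is one sine cycle (positive lobe first),
resembling an extracellular action potential; `triangular` is a single
positive triangle. Spike times are snapped to the sample grid so
noiseless recovery is exact to the sample.

Randomness uses one `SeedSequence` split into a spike stream and a noise
stream, so changing `noise_sd` never moves spike times (fixed-truth SNR
sweeps), and the same seed reproduces files byte-for-byte.

What the generator does **not** emulate — hence what passing tests do
not show about real data: waveform variability within a unit,
electrode drift, superimposed spikes, non-Gaussian or nonstationary
noise, movement artifacts, background (non-burst) firing, and real
video. Recovery rates here bound the algorithmic error, not biological
difficulty.

## Pipeline

Fixed order: load signals → apply filters → read epochs → peaks per
discriminator → bursts per detector → RAUC → write outputs. Detection
and RAUC use the filtered trace for channels named by a filter and the
raw trace otherwise. Logging goes to standard error; results only to
files; the pipeline is deterministic given its inputs. Exit codes:
0 ok, 1 configuration problem, 2 runtime failure.

## Test problem sizes

The suite favors exhaustive small problems over sampled large ones: all
82,160 grid spike trains for burst detection; 120+ random noise traces
against the per-sample peak-scan oracle; 1000 random specs for the sync
round trip; 20 s recordings (100k samples) for module tests and the full
default 60 s recording for the end-to-end recovery checks. The whole
suite runs in well under a minute.
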