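# Dataset configuration format

A configuration file is a UTF-8 YAML document whose top level is a
mapping from **dataset names** to configuration blocks. Several
datasets (or alternate processing set-ups for one dataset) can live in
one file. Every key except `data_file` is optional; omitting a section
disables the corresponding feature. Unknown keys are warned about and
ignored, never fatal, so files written against a newer schema still
load.

Units throughout: times in **seconds**, frequencies in **Hz**,
amplitudes in the **signal's native units** as declared per channel.

```yaml
feeding experiment:                     # dataset name (unique per file)
  description: Aplysia feeding with force transducer
  data_dir: feeding-data                # base for the relative paths below
  data_file: signals.csv                # REQUIRED: signal file
  video_file: behavior.mp4              # associated video (not decoded here)

  # --- video synchronization ---------------------------------------
  video_offset: -2.51         # signal-timeline time of video frame 0;
                              # negative when the camera started first
  video_rate_factor: 1.0      # corrected video clock = recorded clock x factor
  video_jumps:                # skipped video sections
    - [120.0, 5.0]            # at signal time 120 s, skip 5 s of video

  # --- display -----------------------------------------------------
  plots:
    - {channel: BN2, units: uV, ylim: [-150, 150]}
    - {channel: Force, ylim: [-1, 5]}

  # --- filtering (zero-phase Butterworth, default order 2) ---------
  filters:
    - {channel: Force, lowpass: 5}          # Hz; highpass/lowpass/order
    - {channel: BN2, highpass: 10, lowpass: 1000, order: 4}

  # --- epoch encoder -----------------------------------------------
  epoch_encoder:
    output_file: epochs.csv               # CSV: start_s,end_s,label
    labels: [B38 activity, B3/B6/B9 activity]

  # --- peak detection ----------------------------------------------
  amplitude_discriminators:
    - name: B38                           # unit name (unique)
      channel: BN2
      amplitude: [10, 30]                 # window [lo, hi]; must not
                                          # straddle zero
      epoch_label: B38 activity           # optional epoch constraint
    - {name: B6/B9, channel: BN2, amplitude: [40, 120],
       epoch_label: B3/B6/B9 activity}

  # --- burst detection ---------------------------------------------
  burst_detectors:
    - {unit: B38, f_init: 10, f_term: 5}  # Hz; unit must name a
                                          # discriminator; f_init >= f_term

  # --- rectified area under the curve ------------------------------
  rauc:
    channel: Force
    baseline: mean                        # none | mean | median
    bin_duration: 0.5                     # seconds

  # --- sidecar metadata for raw binary signal files ----------------
  signal_meta:                            # required iff data_file is binary
    fs: 5000                              # Hz
    t_start: 0.0
    channels:
      - {name: BN2, units: uV}
      - {name: Force, units: mN}
```

## Paths

Relative paths are joined first against `data_dir` (if set), then
against the directory of the configuration file; absolute paths pass
through unchanged. Existence is checked when data are loaded, not when
the file is parsed.

## Signal file dialects

* **Delimited text** (`.csv`/`.txt`/`.tsv`): header row `time` plus one
  column per channel; the time column must be uniformly spaced
  (relative tolerance 1e-6) and determines the sampling rate.
* **Raw binary** (any other extension): sample-interleaved
  little-endian float32; `signal_meta` supplies the sampling rate,
  channel names and units.

## Annotation files

Epoch CSVs have the exact header `start_s,end_s,label`; event CSVs
`time_s,label`. Epochs are half-open intervals `[start, end)`.

## Validation rules

* dataset names non-empty and unique; `data_file` present;
* `ylim` increasing; filter cutoffs below Nyquist, `highpass < lowpass`;
* discriminator windows increasing and zero-free; discriminator names
  unique; every burst detector references a discriminator;
  `f_init ≥ f_term > 0`;
* `video_rate_factor > 0`, jump skip durations ≥ 0, jump times strictly
  increasing.

Violations raise a structured error naming the dataset and field
(`ephysync validate <file>` prints them and exits 1).
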