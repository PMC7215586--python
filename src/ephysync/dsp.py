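"""Signal conditioning: zero-phase IIR filtering and rectified area
under the curve (RAUC).

Filtering uses Butterworth designs applied forward-backward
(``sosfiltfilt``), so the pass/stop behavior is squared relative to a
single pass but the phase response is zero — peak times are not shifted,
which matters because spike detection runs on the filtered trace.

RAUC is the binned form of integrated EMG (iEMG): optionally remove a
baseline (mean or median of the whole channel), full-wave rectify
(absolute value), then integrate in consecutive bins of fixed duration.
Each bin's value is the time integral (sample sum x 1/fs) in
signal-units x seconds; a trailing incomplete bin is dropped so bins stay
comparable.  The integration acts as a smoother with timescale set by the
bin size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import SignalSet

__all__ = ["FilterSpec", "RaucSpec", "apply_filter", "rauc"]

_BASELINES = ("none", "mean", "median")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter for one channel; at least one cutoff required."""

    channel: str
    highpass_hz: float | None = None
    lowpass_hz: float | None = None
    order: int = 2

    def __post_init__(self):
        if self.highpass_hz is None and self.lowpass_hz is None:
            raise ValueError(
                f"filter for channel {self.channel!r}: at least one of "
                "highpass_hz/lowpass_hz is required"
            )
        if self.highpass_hz is not None and self.highpass_hz < 0:
            raise ValueError(f"highpass_hz must be >= 0, got {self.highpass_hz}")
        if (
            self.highpass_hz is not None
            and self.lowpass_hz is not None
            and not self.highpass_hz < self.lowpass_hz
        ):
            raise ValueError(
                f"highpass_hz ({self.highpass_hz}) must be below lowpass_hz "
                f"({self.lowpass_hz})"
            )
        if not (isinstance(self.order, int) and self.order >= 1):
            raise ValueError(f"order must be a positive integer, got {self.order}")


@dataclass(frozen=True)
class RaucSpec:
    """RAUC parameters for one channel."""

    channel: str
    baseline: str = "none"
    bin_duration: float = 0.1

    def __post_init__(self):
        if self.baseline not in _BASELINES:
            raise ValueError(
                f"baseline must be one of {_BASELINES}, got {self.baseline!r}"
            )
        if not self.bin_duration > 0:
            raise ValueError(f"bin_duration must be > 0, got {self.bin_duration}")


def apply_filter(sig: SignalSet, spec: FilterSpec) -> SignalSet:
    """Zero-phase Butterworth filter of one channel; timestamps unchanged."""
    nyquist = sig.fs / 2
    for name, cutoff in (("highpass_hz", spec.highpass_hz), ("lowpass_hz", spec.lowpass_hz)):
        if cutoff is not None and cutoff >= nyquist:
            raise ValueError(
                f"{name}={cutoff} is at or above the Nyquist frequency "
                f"{nyquist} Hz"
            )
    if spec.highpass_hz is not None and spec.lowpass_hz is not None:
        sos = sps.butter(
            spec.order, [spec.highpass_hz, spec.lowpass_hz], btype="bandpass",
            fs=sig.fs, output="sos",
        )
    elif spec.highpass_hz is not None:
        sos = sps.butter(spec.order, spec.highpass_hz, btype="highpass",
                         fs=sig.fs, output="sos")
    else:
        sos = sps.butter(spec.order, spec.lowpass_hz, btype="lowpass",
                         fs=sig.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.channel(spec.channel))
    return sig.with_channel(spec.channel, filtered)


def rauc(sig: SignalSet, spec: RaucSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rectified area under the curve in fixed-duration bins.

    Returns ``(bin_starts, values)``: the start time of each complete bin
    and its integral of ``|x - baseline|`` in signal-units x seconds.

    Raises ``ValueError`` if the signal is shorter than one bin.
    """
    x = sig.channel(spec.channel)
    per_bin = int(round(spec.bin_duration * sig.fs))
    if per_bin < 1 or len(x) < per_bin:
        raise ValueError(
            f"signal duration {sig.duration:g} s is shorter than one "
            f"{spec.bin_duration:g} s bin"
        )
    if spec.baseline == "mean":
        baseline = x.mean()
    elif spec.baseline == "median":
        baseline = np.median(x)
    else:
        baseline = 0.0
    rectified = np.abs(x - baseline)
    n_bins = len(x) // per_bin
    values = rectified[: n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1) / sig.fs
    bin_starts = sig.t_start + np.arange(n_bins) * (per_bin / sig.fs)
    return bin_starts, values
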