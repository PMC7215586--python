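"""Amplitude-window spike discrimination and firing-frequency burst detection.

In extracellular whole-nerve recordings, action potentials from different
neurons appear as voltage peaks whose size reflects axon diameter and
electrode proximity; in many preparations units are identifiable purely by
peak amplitude and by when they fire within a motor pattern.  An
:class:`AmplitudeDiscriminator` captures this classic workflow: a lower and
upper amplitude threshold (a *window*) on one channel, optionally
restricted to periods carrying a given epoch label.  Local maxima (or, for
a negative window, local minima) falling inside the window form one
:class:`SpikeTrain` per discriminator.

Bursts — periods of high-frequency firing — are then segmented from a
spike train by two thresholds on the instantaneous firing frequency (the
reciprocal of an interspike interval, ISI): a burst *opens* at a spike
whose following ISI-frequency reaches ``f_init`` and keeps absorbing
spikes while ISI-frequencies stay at or above ``f_term``.  Spikes whose
ISIs never qualify (typically a lone spike before or after a burst) are
excluded.  A burst spans first to last member spike and always has at
least two spikes, since frequency is undefined for one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DetectError
from .io import Epoch, SignalSet

__all__ = [
    "AmplitudeDiscriminator",
    "SpikeTrain",
    "BurstDetectorSpec",
    "Burst",
    "find_peaks",
    "detect_bursts",
]


@dataclass(frozen=True)
class AmplitudeDiscriminator:
    """Amplitude window defining one unit on one channel.

    The window must not straddle zero: either both bounds are >= 0 (peaks
    are local maxima) or both <= 0 (peaks are local minima).
    """

    name: str
    channel: str
    amp_lo: float
    amp_hi: float
    epoch_label: str | None = None

    def __post_init__(self):
        if not self.amp_lo < self.amp_hi:
            raise DetectError(
                f"discriminator {self.name!r}: amp_lo ({self.amp_lo}) must be "
                f"below amp_hi ({self.amp_hi})"
            )
        if self.amp_lo < 0 < self.amp_hi:
            raise DetectError(
                f"discriminator {self.name!r}: window [{self.amp_lo}, "
                f"{self.amp_hi}] straddles zero"
            )

    @property
    def is_negative(self) -> bool:
        return self.amp_hi <= 0


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) and peak amplitudes for one unit."""

    unit: str
    times: np.ndarray
    amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        amps = self.amplitudes
        if amps is None:
            amps = np.full(len(times), np.nan)
        object.__setattr__(self, "amplitudes", np.asarray(amps, dtype=float))
        if len(self.amplitudes) != len(times):
            raise DetectError("one amplitude required per spike")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DetectError(f"spike train {self.unit!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class BurstDetectorSpec:
    """Initiation/termination firing-frequency thresholds for one unit."""

    unit: str
    f_init: float
    f_term: float

    def __post_init__(self):
        if not self.f_term > 0:
            raise DetectError(f"f_term must be > 0, got {self.f_term}")
        if not self.f_init >= self.f_term:
            raise DetectError(
                f"f_init ({self.f_init}) must be >= f_term ({self.f_term})"
            )


@dataclass(frozen=True)
class Burst:
    """A contiguous high-frequency run of spikes, first to last spike."""

    start: float
    end: float
    n_spikes: int

    def __post_init__(self):
        if self.n_spikes < 2:
            raise DetectError("a burst needs at least 2 spikes")
        if not self.start < self.end:
            raise DetectError(f"burst start {self.start} must precede end {self.end}")


def find_peaks(
    sig: SignalSet,
    d: AmplitudeDiscriminator,
    epochs: list[Epoch] | None = None,
) -> SpikeTrain:
    """Locate peaks of one channel inside an amplitude window.

    For a non-negative window, peaks are strict-left local maxima
    (``x[i-1] < x[i] >= x[i+1]``, so a plateau counts once, at its first
    sample) whose value lies in ``[amp_lo, amp_hi]``; for a negative window,
    the mirror-image local minima.  The first and last samples are never
    peaks.  When ``d.epoch_label`` is set, only peaks whose time falls in
    the union of half-open epochs bearing that label are kept, and
    ``epochs`` must be supplied.
    """
    x = sig.channel(d.channel)
    if d.epoch_label is not None and epochs is None:
        raise DetectError(
            f"discriminator {d.name!r} requires epochs labeled "
            f"{d.epoch_label!r}, but no epochs were supplied"
        )
    if d.is_negative:
        idx = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1
    else:
        idx = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1
    values = x[idx]
    keep = (values >= d.amp_lo) & (values <= d.amp_hi)
    idx, values = idx[keep], values[keep]
    times = sig.t_start + idx / sig.fs
    if d.epoch_label is not None:
        mask = np.zeros(len(times), dtype=bool)
        for e in epochs:
            if e.label == d.epoch_label:
                mask |= (times >= e.start) & (times < e.end)
        times, values = times[mask], values[mask]
    return SpikeTrain(unit=d.name, times=times, amplitudes=values)


def detect_bursts(train: SpikeTrain, spec: BurstDetectorSpec) -> list[Burst]:
    """Segment a spike train into bursts by ISI-frequency thresholds.

    Scanning left to right over instantaneous frequencies
    ``f_i = 1 / (t[i+1] - t[i])``: a burst opens at spike *i* when
    ``f_i >= f_init`` and extends over spike ``j+1`` while
    ``f_j >= f_term``; it closes at the first spike whose following ISI
    fails ``f_term`` (or at the last spike).  Scanning resumes after the
    closing spike, so bursts are disjoint and ordered.
    """
    t = np.asarray(train.times, dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DetectError("spike times must be strictly increasing")
    freqs = 1.0 / np.diff(t)
    bursts: list[Burst] = []
    i = 0
    while i < len(freqs):
        if freqs[i] >= spec.f_init:
            j = i + 1
            while j < len(freqs) and freqs[j] >= spec.f_term:
                j += 1
            bursts.append(Burst(start=t[i], end=t[j], n_spikes=j - i + 1))
            i = j + 1
        else:
            i += 1
    return bursts
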