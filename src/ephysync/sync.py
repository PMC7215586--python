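"""Mapping between the signal-acquisition timeline and the video timeline.

Electrophysiology signals and behavioral video are usually captured by
independent acquisition systems whose clocks start at different moments and
may drift or pause.  A :class:`SyncSpec` describes the mapping from signal
time to video time with three ingredients:

* ``video_offset`` — the signal-timeline time at which video frame 0 was
  captured.  Negative when video capture began before signal acquisition
  (a camera started 2.51 s early gives ``video_offset = -2.51``).
* ``rate_factor`` — multiplicative correction for video clock inaccuracy;
  corrected video clock = recorded video clock x ``rate_factor``.
* ``jumps`` — sections of video to skip: at signal time ``t_j`` the video
  jumps forward by ``skip_j`` seconds (e.g. the camera kept rolling between
  trials while the recording was paused).

The forward map is

    video(t) = rate_factor * (t - video_offset) + sum of skip_j for t_j <= t

which is strictly increasing and therefore invertible; video times that fall
inside a skipped section invert to the jump's signal time.

Counter-based offset estimation supports the common lab protocol in which a
digital counter incrementing at a fixed rate (10 Hz in the feeding
experiments this tool was built around) is filmed by the camera while its
pulses are recorded alongside the signals: reading the counter value off a
video frame yields the video_offset directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import SyncError

__all__ = [
    "SyncSpec",
    "signal_to_video_time",
    "video_to_signal_time",
    "frame_index_at",
    "estimate_offset_from_counter",
]


@dataclass(frozen=True)
class SyncSpec:
    """Parameters aligning the signal timeline with the video timeline."""

    video_offset: float = 0.0
    rate_factor: float = 1.0
    #: (signal_time, skip_duration) pairs, sorted by signal_time
    jumps: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not math.isfinite(self.video_offset):
            raise SyncError("video_offset must be finite")
        if not (self.rate_factor > 0):
            raise SyncError(f"rate_factor must be > 0, got {self.rate_factor}")
        jumps = tuple((float(t), float(d)) for t, d in self.jumps)
        object.__setattr__(self, "jumps", jumps)
        for i, (t, d) in enumerate(jumps):
            if d < 0:
                raise SyncError(f"jump {i}: skip_duration must be >= 0, got {d}")
            if i > 0 and t <= jumps[i - 1][0]:
                raise SyncError("jumps must be sorted strictly increasing in signal_time")


def signal_to_video_time(t: float, spec: SyncSpec) -> float:
    """Video-timeline time corresponding to signal-timeline time ``t``."""
    skipped = sum(d for tj, d in spec.jumps if tj <= t)
    return spec.rate_factor * (t - spec.video_offset) + skipped


def video_to_signal_time(v: float, spec: SyncSpec) -> float:
    """Signal-timeline time corresponding to video-timeline time ``v``.

    Exact inverse of :func:`signal_to_video_time` where that map is
    continuous.  A video time inside a skipped span maps to the signal time
    of the jump itself.
    """
    r = spec.rate_factor
    skipped = 0.0
    for tj, d in spec.jumps:
        v_at_jump = r * (tj - spec.video_offset) + skipped
        if v < v_at_jump:
            break
        skipped += d
        if v < v_at_jump + d:
            # inside the skipped span [v_at_jump, v_at_jump + d)
            return tj
    return (v - skipped) / r + spec.video_offset


def frame_index_at(t: float, spec: SyncSpec, fps: float) -> int:
    """Index of the video frame displayed at signal time ``t``.

    The displayed frame is the last frame at or before the cursor
    (``floor(video_time * fps)``), clamped at 0 for times before the start
    of the video.
    """
    if not (fps > 0):
        raise SyncError(f"fps must be > 0, got {fps}")
    return max(0, math.floor(signal_to_video_time(t, spec) * fps))


def estimate_offset_from_counter(
    count: int,
    video_time_of_reading: float,
    pulse_times: Sequence[float],
) -> float:
    """Estimate ``video_offset`` from a filmed pulse counter.

    ``count`` is the counter value read off a video frame at video time
    ``video_time_of_reading`` (1-indexed: after the k-th pulse the counter
    shows k); ``pulse_times`` are the recorded signal-timeline times of the
    pulses.  Returns the signal-timeline time of video frame 0, directly
    usable as ``SyncSpec.video_offset``.
    """
    if not 1 <= count <= len(pulse_times):
        raise SyncError(
            f"counter value {count} out of range for {len(pulse_times)} recorded pulses"
        )
    return float(pulse_times[count - 1]) - float(video_time_of_reading)
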