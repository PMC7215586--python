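"""Signal and annotation file I/O, plus epoch algebra.

Two interchange dialects are supported for multichannel signals:

* **delimited text** — CSV with a header row of ``time`` followed by one
  column per channel; the time column must be uniformly spaced (relative
  tolerance 1e-6) and determines the sampling rate;
* **raw binary** — sample-interleaved little-endian float32 with a sidecar
  :class:`SignalMeta` (sampling rate, channel names, units), normally
  carried inside the dataset configuration.

Annotations follow the epoch/event model: an :class:`Epoch` is a labeled
half-open time interval ``[start, end)`` (a behavior, a motor-pattern
phase), an :class:`Event` a labeled time point.  Both are exchanged as CSV
with fixed headers (``start_s,end_s,label`` / ``time_s,label``).

Epoch algebra mirrors the two clean-up operations an annotation workflow
needs: coalescing same-label epochs separated by at most a tolerance
(:func:`merge_adjacent`) and making a sorted sequence contiguous by
extending each epoch's end to its successor's start (:func:`fill_gaps`).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LoadError

__all__ = [
    "SignalMeta",
    "SignalSet",
    "Epoch",
    "Event",
    "read_signals",
    "write_signals",
    "read_epochs",
    "write_epochs",
    "read_events",
    "write_events",
    "merge_adjacent",
    "fill_gaps",
]

_TEXT_EXTENSIONS = {".csv", ".txt", ".tsv"}
_TIME_FORMAT = "%.9f"  # annotation times; 1 ns resolution


@dataclass(frozen=True)
class SignalMeta:
    """Sidecar metadata describing a raw binary signal file."""

    fs: float
    channel_names: tuple[str, ...]
    units: tuple[str, ...] = ()
    t_start: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        units = tuple(self.units) if self.units else ("",) * len(self.channel_names)
        if len(units) != len(self.channel_names):
            raise LoadError(
                f"{len(units)} units given for {len(self.channel_names)} channels"
            )
        object.__setattr__(self, "units", units)
        if not self.fs > 0:
            raise LoadError(f"sampling rate must be > 0, got {self.fs}")


@dataclass
class SignalSet:
    """Regularly sampled multichannel signal.

    ``samples`` has shape ``(n_samples, n_channels)``; sample *i* of every
    channel occurs at time ``t_start + i / fs``.
    """

    channel_names: list[str]
    units: list[str]
    fs: float
    t_start: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_channels)")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[1]} sample columns for "
                f"{len(self.channel_names)} channel names"
            )
        if len(self.units) != len(self.channel_names):
            raise ValueError("one units string required per channel")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Samples of one channel as a 1-D view."""
        return self.samples[:, self.channel_index(name)]

    def with_channel(self, name: str, data: np.ndarray) -> "SignalSet":
        """Copy of this set with one channel's samples replaced."""
        i = self.channel_index(name)
        samples = self.samples.copy()
        samples[:, i] = data
        return SignalSet(
            list(self.channel_names), list(self.units), self.fs, self.t_start, samples
        )


@dataclass(frozen=True, order=True)
class Epoch:
    """Labeled half-open time interval [start, end)."""

    start: float
    end: float
    label: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError("epoch bounds must be finite")
        if self.end < self.start:
            raise ValueError(f"epoch end {self.end} precedes start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True, order=True)
class Event:
    """Labeled time point."""

    time: float
    label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.time):
            raise ValueError("event time must be finite")


# ---------------------------------------------------------------------------
# signal files


def read_signals(path: str | os.PathLike, meta: SignalMeta | None = None) -> SignalSet:
    """Load a multichannel signal file.

    Files with a ``.csv``/``.txt``/``.tsv`` extension are read as delimited
    text (header row: time plus channel names); anything else is read as raw
    sample-interleaved little-endian float32, which requires ``meta``.
    """
    path = os.fspath(path)
    if os.path.splitext(path)[1].lower() in _TEXT_EXTENSIONS:
        return _read_signals_text(path, meta)
    return _read_signals_binary(path, meta)


def _read_signals_text(path: str, meta: SignalMeta | None) -> SignalSet:
    sep = "\t" if path.lower().endswith(".tsv") else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise LoadError(f"{path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise LoadError(f"{path}: need a time column plus at least one channel")
    if frame.shape[0] < 2:
        raise LoadError(f"{path}: need at least two samples to determine fs")
    bad = frame.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise LoadError(f"{path}: missing or unparseable value in data row {row}")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    dt0 = (t[-1] - t[0]) / (len(t) - 1)
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > 1e-6 * abs(dt0)):
        raise LoadError(f"{path}: time column is not uniformly spaced")
    names = [str(c) for c in frame.columns[1:]]
    if meta is not None and list(meta.channel_names) != names:
        raise LoadError(
            f"{path}: header channels {names} do not match metadata "
            f"{list(meta.channel_names)}"
        )
    units = list(meta.units) if meta is not None else [""] * len(names)
    return SignalSet(
        channel_names=names,
        units=units,
        fs=1.0 / dt0,
        t_start=float(t[0]),
        samples=frame.iloc[:, 1:].to_numpy(dtype=float),
    )


def _read_signals_binary(path: str, meta: SignalMeta | None) -> SignalSet:
    if meta is None:
        raise LoadError(f"{path}: binary signal files require sidecar metadata")
    raw = np.fromfile(path, dtype="<f4")
    n_ch = len(meta.channel_names)
    if raw.size % n_ch:
        raise LoadError(
            f"{path}: {raw.size} samples not divisible by {n_ch} channels"
        )
    return SignalSet(
        channel_names=list(meta.channel_names),
        units=list(meta.units),
        fs=meta.fs,
        t_start=meta.t_start,
        samples=raw.reshape(-1, n_ch).astype(float),
    )


def write_signals(sig: SignalSet, path: str | os.PathLike) -> None:
    """Write a signal file in the dialect implied by the extension.

    The binary dialect round-trips samples bit-exactly at float32
    precision; the text dialect is limited by decimal formatting.
    """
    path = os.fspath(path)
    if os.path.splitext(path)[1].lower() in _TEXT_EXTENSIONS:
        sep = "\t" if path.lower().endswith(".tsv") else ","
        frame = pd.DataFrame(sig.samples, columns=sig.channel_names)
        frame.insert(0, "time", sig.times)
        frame.to_csv(path, sep=sep, index=False, float_format="%.10g")
    else:
        sig.samples.astype("<f4").tofile(path)


# ---------------------------------------------------------------------------
# annotation files


def read_epochs(path: str | os.PathLike) -> list[Epoch]:
    """Read an epoch CSV (header ``start_s,end_s,label``), sorted by start."""
    rows = _read_annotation_rows(path, ("start_s", "end_s", "label"))
    epochs = []
    for i, (start, end, label) in enumerate(rows):
        try:
            epochs.append(Epoch(float(start), float(end), label))
        except ValueError as exc:
            raise LoadError(f"{os.fspath(path)}: data row {i + 1}: {exc}") from exc
    return sorted(epochs)


def write_epochs(epochs: Iterable[Epoch], path: str | os.PathLike) -> None:
    """Write epochs to CSV, sorted by start."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "label"])
        for e in sorted(epochs):
            writer.writerow([_TIME_FORMAT % e.start, _TIME_FORMAT % e.end, e.label])


def read_events(path: str | os.PathLike) -> list[Event]:
    """Read an event CSV (header ``time_s,label``), sorted by time."""
    rows = _read_annotation_rows(path, ("time_s", "label"))
    events = []
    for i, (time, label) in enumerate(rows):
        try:
            events.append(Event(float(time), label))
        except ValueError as exc:
            raise LoadError(f"{os.fspath(path)}: data row {i + 1}: {exc}") from exc
    return sorted(events)


def write_events(events: Iterable[Event], path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "label"])
        for e in sorted(events):
            writer.writerow([_TIME_FORMAT % e.time, e.label])


def _read_annotation_rows(
    path: str | os.PathLike, header: tuple[str, ...]
) -> list[tuple[str, ...]]:
    path = os.fspath(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise LoadError(f"{path}: empty file, expected header {','.join(header)}")
        if [c.strip() for c in got] != list(header):
            raise LoadError(
                f"{path}: expected header {','.join(header)}, got {','.join(got)}"
            )
        rows = []
        for i, row in enumerate(reader):
            if not row:
                continue
            if len(row) != len(header):
                raise LoadError(
                    f"{path}: data row {i + 1} has {len(row)} fields, expected "
                    f"{len(header)}"
                )
            rows.append(tuple(row))
    return rows


# ---------------------------------------------------------------------------
# epoch algebra


def merge_adjacent(epochs: Sequence[Epoch], tolerance: float = 0.0) -> list[Epoch]:
    """Coalesce same-label epochs whose gap is at most ``tolerance``.

    Overlapping same-label epochs (negative gap) are merged as well.  The
    result is sorted; gaps between remaining same-label epochs all exceed
    ``tolerance``.  Order-insensitive and idempotent.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    merged: list[Epoch] = []
    by_label = sorted(epochs, key=lambda e: (e.label, e.start, e.end))
    for _, group in groupby(by_label, key=lambda e: e.label):
        current = next(group)
        for e in group:
            if e.start - current.end <= tolerance:
                if e.end > current.end:
                    current = replace(current, end=e.end)
            else:
                merged.append(current)
                current = e
        merged.append(current)
    return sorted(merged)


def fill_gaps(epochs: Sequence[Epoch]) -> list[Epoch]:
    """Eliminate gaps by extending each epoch's end to its successor's start.

    Input must be non-overlapping (touching is fine).  The overall span
    [first start, last end] is conserved, and the operation is idempotent.
    """
    ordered = sorted(epochs)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping epochs: [{a.start}, {a.end}) {a.label!r} and "
                f"[{b.start}, {b.end}) {b.label!r}"
            )
    return [
        replace(a, end=b.start) if b.start > a.end else a
        for a, b in zip(ordered, ordered[1:])
    ] + ordered[-1:]
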