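"""Synthetic datasets with known ground truth.

The generator emulates the shape of an extracellular feeding-behavior
recording: a nerve channel carrying spike waveforms from a few units of
well-separated amplitudes, firing in bursts, embedded in Gaussian noise;
a slow force-like channel for RAUC and filtering; labeled epochs covering
the active periods; counter pulses for video-offset estimation; and a
dataset configuration whose amplitude discriminators (windows
``[0.5 A, 1.5 A]`` around each unit's amplitude ``A``) and burst detectors
(initiation/termination frequencies at half and a quarter of each unit's
within-burst rate) recover the ground truth.

Defaults follow the acquisition conditions the tool targets: 5000 Hz
sampling, a 10 Hz synchronization counter, 30 fps video starting 2.51 s
before the signals, and three units reminiscent of the identified
*Aplysia* buccal motor neurons distinguishable by spike size on BN2.

Generation is deterministic given the seed, and the random stream is
split so that changing ``noise_sd`` never changes spike times —
enabling SNR sweeps against fixed truth.  Bursts are kept non-overlapping
(within and across units, by rejection sampling) so the ground truth is
unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .config import DatasetConfig, EpochEncoderSpec, serialize_config
from .detect import AmplitudeDiscriminator, Burst, BurstDetectorSpec
from .dsp import FilterSpec, RaucSpec
from .io import Epoch, SignalMeta, SignalSet, write_epochs, write_signals
from .sync import SyncSpec, signal_to_video_time

__all__ = [
    "UnitSpec",
    "SynthSpec",
    "GroundTruth",
    "SynthBundle",
    "generate",
    "write_dataset",
    "load_ground_truth",
]

_TEMPLATES = ("biphasic", "triangular")

# placement geometry (seconds): guard between any two bursts' padded spans,
# epoch padding around a burst, and margin kept clear at the record's ends
_CROSS_GUARD = 0.06
_EPOCH_PAD = 0.03
_EDGE_MARGIN = 0.5


@dataclass(frozen=True)
class UnitSpec:
    """One synthetic unit: waveform, amplitude, and bursting statistics."""

    name: str
    amplitude: float
    template: str = "biphasic"
    template_width: float = 0.001
    burst_rate: float = 0.5           # reciprocal of the minimum inter-burst gap
    within_burst_rate: float = 20.0   # mean instantaneous frequency inside bursts
    n_bursts: int = 3

    def __post_init__(self):
        if self.template not in _TEMPLATES:
            raise ValueError(f"template must be one of {_TEMPLATES}, got {self.template!r}")
        if not self.amplitude > 0:
            raise ValueError(f"unit {self.name!r}: amplitude must be > 0")
        if not self.within_burst_rate > self.burst_rate:
            raise ValueError(
                f"unit {self.name!r}: within_burst_rate ({self.within_burst_rate}) "
                f"must exceed burst_rate ({self.burst_rate})"
            )
        if not (self.template_width > 0 and self.n_bursts >= 0):
            raise ValueError(f"unit {self.name!r}: bad template_width or n_bursts")


def _default_units() -> tuple[UnitSpec, ...]:
    # amplitudes a factor 4 apart so the [0.5A, 1.5A] windows are disjoint
    return (
        UnitSpec("B38", amplitude=20.0, template="triangular", within_burst_rate=20.0),
        UnitSpec("B6/B9", amplitude=80.0, template="biphasic", within_burst_rate=25.0),
        UnitSpec("B3", amplitude=320.0, template="biphasic", within_burst_rate=15.0),
    )


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    duration: float = 60.0
    fs: float = 5000.0
    noise_sd: float = 2.0
    units: tuple[UnitSpec, ...] = field(default_factory=_default_units)
    epoch_label: str = "activity"
    video_offset: float = -2.51
    counter_rate: float = 10.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))
        if not (self.duration > 0 and self.fs > 0 and self.counter_rate > 0):
            raise ValueError("duration, fs and counter_rate must all be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        amps = sorted(u.amplitude for u in self.units)
        for a, b in zip(amps, amps[1:]):
            if b - a < 4 * self.noise_sd:
                raise ValueError(
                    f"unit amplitudes {a} and {b} are closer than 4 x noise_sd "
                    f"({4 * self.noise_sd}); ground truth would be ambiguous"
                )
            if not b > 3 * a:
                raise ValueError(
                    f"unit amplitudes {a} and {b} give overlapping "
                    f"[0.5A, 1.5A] discriminator windows"
                )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SynthSpec":
        kwargs = dict(d)
        if "units" in kwargs:
            kwargs["units"] = tuple(
                u if isinstance(u, UnitSpec) else UnitSpec(**u) for u in kwargs["units"]
            )
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator embedded, keyed by unit name."""

    spike_times: dict[str, np.ndarray]
    spike_indices: dict[str, np.ndarray]
    bursts: dict[str, list[Burst]]
    epochs: list[Epoch]
    video_offset: float
    counter_pulse_times: np.ndarray
    #: (counter value, video time at which it was read) — as if read off a frame
    counter_reading: tuple[int, float]


@dataclass
class SynthBundle:
    signals: SignalSet
    truth: GroundTruth
    config: DatasetConfig
    spec: SynthSpec


def _template_samples(kind: str, width: float, fs: float) -> tuple[np.ndarray, int]:
    """Unit-peak template samples and the index of the peak sample."""
    n = max(3, int(round(width * fs)))
    if kind == "triangular":
        p = n // 2
        tpl = 1.0 - np.abs(np.arange(n) - p) / p
    else:  # biphasic: one sine cycle, positive lobe first
        tpl = np.sin(2 * np.pi * np.arange(n) / n)
        tpl = tpl / tpl.max()
        p = int(np.argmax(tpl))
    return tpl, p


def generate(spec: SynthSpec) -> SynthBundle:
    """Generate a synthetic dataset, its ground truth, and a matching config.

    Deterministic given ``spec.seed``.  Raises ``ValueError`` when the
    requested bursts cannot be placed without overlap within the duration.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_spikes, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    n_samples = int(round(spec.duration * spec.fs))

    placed: list[tuple[float, float]] = []  # padded burst spans, all units
    spike_times: dict[str, np.ndarray] = {}
    spike_indices: dict[str, np.ndarray] = {}
    bursts: dict[str, list[Burst]] = {}
    epochs: list[Epoch] = []

    for unit in spec.units:
        gap_min = max(1.0 / unit.burst_rate, 5.0 / unit.within_burst_rate)
        unit_spans: list[tuple[float, float]] = []
        all_idx: list[np.ndarray] = []
        unit_bursts: list[Burst] = []
        for _ in range(unit.n_bursts):
            n_spk = int(rng_spikes.integers(5, 11))
            isis = (0.9 + 0.2 * rng_spikes.random(n_spk - 1)) / unit.within_burst_rate
            offsets = np.concatenate(([0.0], np.cumsum(isis)))
            dur = float(offsets[-1])
            hi = spec.duration - dur - _EDGE_MARGIN
            if hi <= _EDGE_MARGIN:
                raise ValueError(
                    f"duration {spec.duration} s too short to place a "
                    f"{dur:.2f} s burst for unit {unit.name!r}"
                )
            for _attempt in range(10_000):
                t0 = float(rng_spikes.uniform(_EDGE_MARGIN, hi))
                span = (t0 - _CROSS_GUARD, t0 + dur + _CROSS_GUARD)
                if any(span[0] < e and s < span[1] for s, e in placed):
                    continue
                if any(
                    t0 - e < gap_min and s - (t0 + dur) < gap_min
                    for s, e in unit_spans
                ):
                    continue
                break
            else:
                raise ValueError(
                    f"could not place {unit.n_bursts} non-overlapping bursts "
                    f"for unit {unit.name!r} in {spec.duration} s"
                )
            placed.append(span)
            unit_spans.append((t0, t0 + dur))
            idx = np.round((t0 + offsets) * spec.fs).astype(int)
            all_idx.append(idx)
            times = idx / spec.fs
            unit_bursts.append(Burst(float(times[0]), float(times[-1]), len(times)))
            epochs.append(
                Epoch(float(times[0]) - _EPOCH_PAD, float(times[-1]) + _EPOCH_PAD,
                      spec.epoch_label)
            )
        idx = np.sort(np.concatenate(all_idx)) if all_idx else np.array([], dtype=int)
        spike_indices[unit.name] = idx
        spike_times[unit.name] = idx / spec.fs
        bursts[unit.name] = sorted(unit_bursts, key=lambda b: b.start)
    epochs.sort()

    # waveforms + noise on the nerve channel, slow clean wave on the force channel
    nerve = rng_noise.normal(0.0, spec.noise_sd, n_samples) if spec.noise_sd > 0 \
        else np.zeros(n_samples)
    for unit in spec.units:
        tpl, p = _template_samples(unit.template, unit.template_width, spec.fs)
        for i in spike_indices[unit.name]:
            nerve[i - p : i - p + len(tpl)] += unit.amplitude * tpl
    t = np.arange(n_samples) / spec.fs
    force = np.sin(2 * np.pi * 0.25 * t)
    signals = SignalSet(
        channel_names=["BN2", "Force"],
        units=["uV", "mN"],
        fs=spec.fs,
        t_start=0.0,
        samples=np.column_stack([nerve, force]),
    )

    sync = SyncSpec(video_offset=spec.video_offset)
    pulses = np.arange(0.0, spec.duration, 1.0 / spec.counter_rate)
    count = max(1, len(pulses) // 2)
    reading = (count, signal_to_video_time(float(pulses[count - 1]), sync))
    truth = GroundTruth(
        spike_times=spike_times,
        spike_indices=spike_indices,
        bursts=bursts,
        epochs=epochs,
        video_offset=spec.video_offset,
        counter_pulse_times=pulses,
        counter_reading=reading,
    )
    config = DatasetConfig(
        name="synthetic",
        description="synthetic nerve + force recording with known ground truth",
        data_file="signals.csv",
        sync=sync,
        epoch_encoder=EpochEncoderSpec("epochs.csv", (spec.epoch_label,)),
        amplitude_discriminators=tuple(
            AmplitudeDiscriminator(
                name=u.name, channel="BN2",
                amp_lo=0.5 * u.amplitude, amp_hi=1.5 * u.amplitude,
                epoch_label=spec.epoch_label,
            )
            for u in spec.units
        ) or None,
        burst_detectors=tuple(
            BurstDetectorSpec(
                unit=u.name,
                f_init=u.within_burst_rate / 2.0,
                f_term=u.within_burst_rate / 4.0,
            )
            for u in spec.units
        ) or None,
        filters=(FilterSpec(channel="Force", lowpass_hz=5.0),),
        rauc=RaucSpec(channel="Force", baseline="mean", bin_duration=0.5),
    )
    return SynthBundle(signals=signals, truth=truth, config=config, spec=spec)


def write_dataset(bundle: SynthBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write signal files (both dialects), epochs, ground truth, and config.

    Returns a mapping of artifact name to path.  Running the pipeline on
    the emitted ``config.yaml`` reproduces the ground truth (exactly when
    ``noise_sd`` is 0).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("signals_text", "signals.csv"),
        ("signals_binary", "signals.raw"),
        ("epochs", "epochs.csv"),
        ("ground_truth", "ground_truth.json"),
        ("config", "config.yaml"),
    ]}
    write_signals(bundle.signals, paths["signals_text"])
    write_signals(bundle.signals, paths["signals_binary"])
    write_epochs(bundle.truth.epochs, paths["epochs"])

    meta = SignalMeta(
        fs=bundle.signals.fs,
        channel_names=tuple(bundle.signals.channel_names),
        units=tuple(bundle.signals.units),
        t_start=bundle.signals.t_start,
    )
    binary_cfg = dataclasses.replace(
        bundle.config, name="synthetic-binary", data_file="signals.raw", signal_meta=meta
    )
    with open(paths["config"], "w", encoding="utf-8") as fh:
        fh.write(serialize_config({
            bundle.config.name: bundle.config,
            "synthetic-binary": binary_cfg,
        }))

    truth = bundle.truth
    doc = {
        "video_offset": truth.video_offset,
        "counter_rate": bundle.spec.counter_rate,
        "counter_pulse_times": [float(x) for x in truth.counter_pulse_times],
        "counter_reading": {
            "count": truth.counter_reading[0],
            "video_time": truth.counter_reading[1],
        },
        "epochs": [[e.start, e.end, e.label] for e in truth.epochs],
        "units": {
            name: {
                "spike_times": [float(x) for x in truth.spike_times[name]],
                "spike_indices": [int(x) for x in truth.spike_indices[name]],
                "bursts": [[b.start, b.end, b.n_spikes] for b in truth.bursts[name]],
            }
            for name in truth.spike_times
        },
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def load_ground_truth(path: str | os.PathLike) -> GroundTruth:
    """Reload a ``ground_truth.json`` written by :func:`write_dataset`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return GroundTruth(
        spike_times={k: np.array(v["spike_times"]) for k, v in doc["units"].items()},
        spike_indices={
            k: np.array(v["spike_indices"], dtype=int) for k, v in doc["units"].items()
        },
        bursts={
            k: [Burst(s, e, n) for s, e, n in v["bursts"]]
            for k, v in doc["units"].items()
        },
        epochs=sorted(Epoch(s, e, l) for s, e, l in doc["epochs"]),
        video_offset=doc["video_offset"],
        counter_pulse_times=np.array(doc["counter_pulse_times"]),
        counter_reading=(
            doc["counter_reading"]["count"], doc["counter_reading"]["video_time"]
        ),
    )
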