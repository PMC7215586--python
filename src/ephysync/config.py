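"""Portable YAML dataset-configuration format: parse, validate, resolve,
serialize.

A configuration file is one top-level YAML mapping from dataset names to
blocks.  A block locates the data (``data_dir``, ``data_file``,
``video_file``), aligns the video (``video_offset``, ``video_rate_factor``,
``video_jumps``), and optionally configures plotting, filtering, the epoch
encoder, amplitude discriminators, burst detectors, and RAUC.  Every
section except ``data_file`` is optional; an omitted section simply
disables that feature.  The full schema with an annotated example lives in
``docs/config_format.md``.

Unknown keys are preserved-but-warned (``ConfigWarning``) rather than
rejected, so files written against a newer schema still load.  All times
are seconds, frequencies Hz, and amplitudes the signal's native units.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from typing import Any, Mapping

import yaml

from .detect import AmplitudeDiscriminator, BurstDetectorSpec
from .dsp import FilterSpec, RaucSpec
from .errors import (
    ConfigParseError,
    ConfigValidationError,
    ConfigWarning,
    DetectError,
    SyncError,
)
from .io import SignalMeta
from .sync import SyncSpec

__all__ = [
    "PlotSpec",
    "EpochEncoderSpec",
    "DatasetConfig",
    "parse_config_file",
    "parse_config_path",
    "resolve_paths",
    "serialize_config",
]


@dataclass(frozen=True)
class PlotSpec:
    """How to display one channel (units override, y-limits)."""

    channel: str
    units: str | None = None
    ylim: tuple[float, float] | None = None

    def __post_init__(self):
        if self.ylim is not None:
            lo, hi = self.ylim
            object.__setattr__(self, "ylim", (float(lo), float(hi)))
            if not lo < hi:
                raise ValueError(f"ylim must be increasing, got {self.ylim}")


@dataclass(frozen=True)
class EpochEncoderSpec:
    """Epoch-encoder settings: where annotations are saved, which labels exist."""

    output_file: str
    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ValueError("epoch encoder needs at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate epoch labels in {labels}")


@dataclass(frozen=True)
class DatasetConfig:
    """Validated content of one named configuration block."""

    name: str
    data_file: str
    description: str | None = None
    data_dir: str | None = None
    video_file: str | None = None
    sync: SyncSpec | None = None
    signal_meta: SignalMeta | None = None
    plots: tuple[PlotSpec, ...] | None = None
    filters: tuple[FilterSpec, ...] | None = None
    epoch_encoder: EpochEncoderSpec | None = None
    amplitude_discriminators: tuple[AmplitudeDiscriminator, ...] | None = None
    burst_detectors: tuple[BurstDetectorSpec, ...] | None = None
    rauc: RaucSpec | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("dataset name must be non-empty")
        if not self.data_file:
            raise ValueError("data_file is required")
        for attr in ("plots", "filters", "amplitude_discriminators", "burst_detectors"):
            value = getattr(self, attr)
            if value is not None:
                object.__setattr__(self, attr, tuple(value))
        if self.amplitude_discriminators is not None:
            names = [d.name for d in self.amplitude_discriminators]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate discriminator names in {names}")
        if self.burst_detectors:
            known = {d.name for d in self.amplitude_discriminators or ()}
            for b in self.burst_detectors:
                if b.unit not in known:
                    raise ValueError(
                        f"burst detector references unknown discriminator "
                        f"{b.unit!r} (have {sorted(known)})"
                    )


# ---------------------------------------------------------------------------
# parsing

_BLOCK_KEYS = {
    "description", "data_dir", "data_file", "video_file",
    "video_offset", "video_rate_factor", "video_jumps",
    "signal_meta", "plots", "filters", "epoch_encoder",
    "amplitude_discriminators", "burst_detectors", "rauc",
}


def parse_config_file(text: str) -> dict[str, DatasetConfig]:
    """Parse a YAML configuration document into named dataset configs.

    Raises :class:`ConfigParseError` (with a line number where available)
    for malformed YAML and :class:`ConfigValidationError` — naming the
    dataset and field — for blocks violating the schema.  Unknown keys
    emit :class:`ConfigWarning`.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else None
        raise ConfigParseError(str(getattr(exc, "problem", None) or exc), line) from exc
    if doc is None:
        return {}
    if not isinstance(doc, Mapping):
        raise ConfigParseError(
            f"top level must be a mapping of dataset names to blocks, "
            f"got {type(doc).__name__}"
        )
    configs: dict[str, DatasetConfig] = {}
    for name, block in doc.items():
        configs[str(name)] = _parse_block(str(name), block)
    return configs


def parse_config_path(path: str | os.PathLike) -> dict[str, DatasetConfig]:
    """Parse a configuration file and resolve its paths against its directory."""
    path = os.fspath(path)
    with open(path, encoding="utf-8") as fh:
        configs = parse_config_file(fh.read())
    base = os.path.dirname(os.path.abspath(path))
    return {name: resolve_paths(cfg, base) for name, cfg in configs.items()}


def _parse_block(name: str, block: Any) -> DatasetConfig:
    if not isinstance(block, Mapping):
        raise ConfigValidationError(
            name, "<block>", f"expected a mapping, got {type(block).__name__}"
        )
    _warn_unknown(name, block, _BLOCK_KEYS)

    def build(field_name, factory, value):
        try:
            return factory(value)
        except (ValueError, TypeError, KeyError, DetectError, SyncError) as exc:
            raise ConfigValidationError(name, field_name, str(exc)) from exc

    sync = None
    if any(k in block for k in ("video_offset", "video_rate_factor", "video_jumps")):
        sync = build("sync", lambda b: _parse_sync(b), block)

    kwargs: dict[str, Any] = {
        "description": _opt_str(name, block, "description"),
        "data_dir": _opt_str(name, block, "data_dir"),
        "video_file": _opt_str(name, block, "video_file"),
        "sync": sync,
    }
    if "data_file" not in block:
        raise ConfigValidationError(name, "data_file", "required key is missing")
    if not isinstance(block["data_file"], str):
        raise ConfigValidationError(
            name, "data_file",
            f"expected a path, got {type(block['data_file']).__name__}",
        )
    kwargs["data_file"] = block["data_file"]
    if "signal_meta" in block:
        kwargs["signal_meta"] = build("signal_meta", _parse_signal_meta, block["signal_meta"])
    if "plots" in block:
        kwargs["plots"] = tuple(
            build(f"plots[{i}]", _parse_plot, p)
            for i, p in enumerate(_as_list(name, "plots", block["plots"]))
        )
    if "filters" in block:
        kwargs["filters"] = tuple(
            build(f"filters[{i}]", _parse_filter, f)
            for i, f in enumerate(_as_list(name, "filters", block["filters"]))
        )
    if "epoch_encoder" in block:
        kwargs["epoch_encoder"] = build(
            "epoch_encoder", _parse_epoch_encoder, block["epoch_encoder"]
        )
    if "amplitude_discriminators" in block:
        kwargs["amplitude_discriminators"] = tuple(
            build(f"amplitude_discriminators[{i}]", _parse_discriminator, d)
            for i, d in enumerate(
                _as_list(name, "amplitude_discriminators", block["amplitude_discriminators"])
            )
        )
    if "burst_detectors" in block:
        kwargs["burst_detectors"] = tuple(
            build(f"burst_detectors[{i}]", _parse_burst_detector, b)
            for i, b in enumerate(_as_list(name, "burst_detectors", block["burst_detectors"]))
        )
    if "rauc" in block:
        kwargs["rauc"] = build("rauc", _parse_rauc, block["rauc"])
    return build("<block>", lambda _: DatasetConfig(name=name, **kwargs), None)


def _warn_unknown(dataset: str, mapping: Mapping, known: set[str], where: str = ""):
    for key in mapping:
        if key not in known:
            warnings.warn(
                f"dataset {dataset!r}: unknown key {key!r}{where} is ignored",
                ConfigWarning,
                stacklevel=3,
            )


def _opt_str(dataset: str, block: Mapping, key: str) -> str | None:
    value = block.get(key)
    if value is None:
        return None
    if not isinstance(value, str):
        raise ConfigValidationError(
            dataset, key, f"expected text, got {type(value).__name__}"
        )
    return value


def _as_list(dataset: str, key: str, value: Any) -> list:
    if not isinstance(value, list):
        raise ConfigValidationError(
            dataset, key, f"expected a list, got {type(value).__name__}"
        )
    return value


def _require(mapping: Mapping, *keys: str) -> list:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ValueError(f"missing required key(s): {', '.join(missing)}")
    return [mapping[k] for k in keys]


def _parse_sync(block: Mapping) -> SyncSpec:
    jumps = block.get("video_jumps") or ()
    return SyncSpec(
        video_offset=float(block.get("video_offset", 0.0)),
        rate_factor=float(block.get("video_rate_factor", 1.0)),
        jumps=tuple((float(t), float(d)) for t, d in jumps),
    )


def _parse_signal_meta(m: Mapping) -> SignalMeta:
    (fs, channels) = _require(m, "fs", "channels")
    names, units = [], []
    for ch in channels:
        if isinstance(ch, str):
            names.append(ch)
            units.append("")
        else:
            names.append(str(_require(ch, "name")[0]))
            units.append(str(ch.get("units", "")))
    return SignalMeta(
        fs=float(fs), channel_names=tuple(names), units=tuple(units),
        t_start=float(m.get("t_start", 0.0)),
    )


def _parse_plot(m: Mapping) -> PlotSpec:
    (channel,) = _require(m, "channel")
    ylim = m.get("ylim")
    return PlotSpec(
        channel=str(channel),
        units=m.get("units"),
        ylim=tuple(float(v) for v in ylim) if ylim is not None else None,
    )


def _parse_filter(m: Mapping) -> FilterSpec:
    (channel,) = _require(m, "channel")
    hp, lp = m.get("highpass"), m.get("lowpass")
    return FilterSpec(
        channel=str(channel),
        highpass_hz=float(hp) if hp is not None else None,
        lowpass_hz=float(lp) if lp is not None else None,
        order=int(m.get("order", 2)),
    )


def _parse_epoch_encoder(m: Mapping) -> EpochEncoderSpec:
    (output_file, labels) = _require(m, "output_file", "labels")
    return EpochEncoderSpec(
        output_file=str(output_file), labels=tuple(str(l) for l in labels)
    )


def _parse_discriminator(m: Mapping) -> AmplitudeDiscriminator:
    (name, channel, amplitude) = _require(m, "name", "channel", "amplitude")
    if not (isinstance(amplitude, (list, tuple)) and len(amplitude) == 2):
        raise ValueError(f"amplitude must be a [lo, hi] pair, got {amplitude!r}")
    label = m.get("epoch_label")
    return AmplitudeDiscriminator(
        name=str(name),
        channel=str(channel),
        amp_lo=float(amplitude[0]),
        amp_hi=float(amplitude[1]),
        epoch_label=str(label) if label is not None else None,
    )


def _parse_burst_detector(m: Mapping) -> BurstDetectorSpec:
    (unit, f_init, f_term) = _require(m, "unit", "f_init", "f_term")
    return BurstDetectorSpec(unit=str(unit), f_init=float(f_init), f_term=float(f_term))


def _parse_rauc(m: Mapping) -> RaucSpec:
    (channel,) = _require(m, "channel")
    return RaucSpec(
        channel=str(channel),
        baseline=str(m.get("baseline", "none")),
        bin_duration=float(m.get("bin_duration", 0.1)),
    )


# ---------------------------------------------------------------------------
# path resolution


def resolve_paths(cfg: DatasetConfig, base: str | os.PathLike) -> DatasetConfig:
    """Resolve the config's relative paths.

    Relative paths are joined first against ``data_dir`` (when set), then
    against ``base`` (normally the directory of the configuration file);
    absolute paths pass through untouched.  File existence is deliberately
    not checked here — that happens at load time.
    """
    base = os.fspath(base)
    data_dir = cfg.data_dir
    if data_dir is not None and not os.path.isabs(data_dir):
        data_dir = os.path.join(base, data_dir)

    def resolve(p: str | None) -> str | None:
        if p is None or os.path.isabs(p):
            return p
        return os.path.join(data_dir if data_dir is not None else base, p)

    epoch_encoder = cfg.epoch_encoder
    if epoch_encoder is not None:
        epoch_encoder = replace(epoch_encoder, output_file=resolve(epoch_encoder.output_file))
    return replace(
        cfg,
        data_dir=data_dir,
        data_file=resolve(cfg.data_file),
        video_file=resolve(cfg.video_file),
        epoch_encoder=epoch_encoder,
    )


# ---------------------------------------------------------------------------
# serialization


def serialize_config(cfgs: Mapping[str, DatasetConfig]) -> str:
    """Render configs back to YAML; ``parse_config_file`` round-trips it."""
    doc = {}
    for name, cfg in cfgs.items():
        block: dict[str, Any] = {}
        if cfg.description is not None:
            block["description"] = cfg.description
        if cfg.data_dir is not None:
            block["data_dir"] = cfg.data_dir
        block["data_file"] = cfg.data_file
        if cfg.video_file is not None:
            block["video_file"] = cfg.video_file
        if cfg.sync is not None:
            block["video_offset"] = cfg.sync.video_offset
            if cfg.sync.rate_factor != 1.0:
                block["video_rate_factor"] = cfg.sync.rate_factor
            if cfg.sync.jumps:
                block["video_jumps"] = [list(j) for j in cfg.sync.jumps]
        if cfg.signal_meta is not None:
            m = cfg.signal_meta
            block["signal_meta"] = {
                "fs": m.fs,
                "t_start": m.t_start,
                "channels": [
                    {"name": n, "units": u} for n, u in zip(m.channel_names, m.units)
                ],
            }
        if cfg.plots is not None:
            block["plots"] = [
                _drop_none({"channel": p.channel, "units": p.units,
                            "ylim": list(p.ylim) if p.ylim else None})
                for p in cfg.plots
            ]
        if cfg.filters is not None:
            block["filters"] = [
                _drop_none({"channel": f.channel, "highpass": f.highpass_hz,
                            "lowpass": f.lowpass_hz, "order": f.order})
                for f in cfg.filters
            ]
        if cfg.epoch_encoder is not None:
            block["epoch_encoder"] = {
                "output_file": cfg.epoch_encoder.output_file,
                "labels": list(cfg.epoch_encoder.labels),
            }
        if cfg.amplitude_discriminators is not None:
            block["amplitude_discriminators"] = [
                _drop_none({"name": d.name, "channel": d.channel,
                            "amplitude": [d.amp_lo, d.amp_hi],
                            "epoch_label": d.epoch_label})
                for d in cfg.amplitude_discriminators
            ]
        if cfg.burst_detectors is not None:
            block["burst_detectors"] = [
                {"unit": b.unit, "f_init": b.f_init, "f_term": b.f_term}
                for b in cfg.burst_detectors
            ]
        if cfg.rauc is not None:
            block["rauc"] = {"channel": cfg.rauc.channel, "baseline": cfg.rauc.baseline,
                             "bin_duration": cfg.rauc.bin_duration}
        doc[name] = block
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False, allow_unicode=True)


def _drop_none(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None}
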