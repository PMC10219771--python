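"""Multichannel recording I/O and timebase alignment.

A recording is stored as one or more wide CSV files (one column per channel,
no timestamp column — time is implicit from the sampling rate and per-file
start offset) plus a JSON session descriptor mapping every column to channel
metadata. Channels sampled at different rates live in separate CSV files so
no NaN padding is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DescriptorMismatchError,
    MetadataError,
    SignalParseError,
)

DEFAULT_EMG_RATE_HZ = 2000.0
DEFAULT_GYRO_RATE_HZ = 148.0

#: The seven muscles analysed per leg.
MUSCLES = (
    "rectus_femoris",
    "vastus_lateralis",
    "vastus_medialis",
    "tibialis_anterior",
    "biceps_femoris",
    "gastrocnemius_medialis",
    "gastrocnemius_lateralis",
)


class ChannelKind(str, Enum):
    EMG = "emg"
    GYRO_X = "gyro_x"
    GYRO_Y = "gyro_y"
    GYRO_Z = "gyro_z"

    @property
    def is_gyro(self) -> bool:
        return self is not ChannelKind.EMG


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled channel.

    Sample ``i`` occurs at time ``t0_s + i / rate_hz`` (seconds from session
    start). Units are mV for EMG and deg/s for gyroscope channels.
    """

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.rate_hz

    def index_at(self, t_s: float) -> int:
        """Nearest sample index to time ``t_s``, ties toward the earlier sample."""
        x = (t_s - self.t0_s) * self.rate_hz
        # round-half-down keeps the mapping deterministic and at most half a
        # sample period off the event time
        i = int(math.ceil(x - 0.5))
        return min(max(i, 0), len(self.samples) - 1)

    def slice_time(self, start_s: float, end_s: float) -> "SampledSignal":
        """Sub-signal covering [start_s, end_s) on the same timebase.

        The end bound is exclusive and may map to one past the last sample,
        so a phase ending exactly at the signal's end keeps its full length.
        """
        i0 = self.index_at(start_s)
        x1 = (end_s - self.t0_s) * self.rate_hz
        i1 = min(max(int(math.ceil(x1 - 0.5)), i0), len(self.samples))
        return SampledSignal(
            self.samples[i0:i1], self.rate_hz, self.t0_s + i0 / self.rate_hz
        )


@dataclass(frozen=True)
class ChannelMeta:
    name: str
    kind: ChannelKind
    side: Side
    muscle: str | None = None

    def __post_init__(self) -> None:
        if self.kind is ChannelKind.EMG and self.muscle is None:
            raise MetadataError(f"EMG channel {self.name!r} must name a muscle")
        if self.muscle is not None and self.muscle not in MUSCLES:
            raise MetadataError(f"unknown muscle {self.muscle!r} on {self.name!r}")

    @property
    def key(self) -> tuple:
        return (self.muscle, self.side, self.kind)


@dataclass
class Recording:
    """A full session: channel metadata mapped to sampled signals."""

    channels: dict[ChannelMeta, SampledSignal]
    label: str = ""
    speed_kmh: float | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for meta in self.channels:
            if meta.key in seen:
                raise MetadataError(
                    f"duplicate (muscle, side, kind) = {meta.key}"
                )
            seen.add(meta.key)

    def __iter__(self) -> Iterator[tuple[ChannelMeta, SampledSignal]]:
        return iter(self.channels.items())

    def find(
        self,
        kind: ChannelKind | None = None,
        side: Side | None = None,
        muscle: str | None = None,
    ) -> list[tuple[ChannelMeta, SampledSignal]]:
        out = []
        for meta, sig in self.channels.items():
            if kind is not None and meta.kind is not kind:
                continue
            if side is not None and meta.side is not side:
                continue
            if muscle is not None and meta.muscle != muscle:
                continue
            out.append((meta, sig))
        return out

    def emg(self, muscle: str, side: Side) -> SampledSignal:
        hits = self.find(kind=ChannelKind.EMG, side=side, muscle=muscle)
        if not hits:
            raise MetadataError(f"no EMG channel for {muscle} / {side.value}")
        return hits[0][1]

    def gyro(self, side: Side, kind: ChannelKind = ChannelKind.GYRO_X) -> SampledSignal:
        hits = self.find(kind=kind, side=side)
        if not hits:
            raise MetadataError(f"no {kind.value} channel on side {side.value}")
        return hits[0][1]

    def emg_muscles(self, side: Side | None = None) -> list[str]:
        names = []
        for meta, _ in self.find(kind=ChannelKind.EMG, side=side):
            if meta.muscle not in names:
                names.append(meta.muscle)
        return names


@dataclass
class _FileGroup:
    path: str
    rate_hz: float
    t0_s: float
    columns: list[ChannelMeta] = field(default_factory=list)


def _meta_to_json(meta: ChannelMeta) -> dict:
    return {
        "name": meta.name,
        "kind": meta.kind.value,
        "muscle": meta.muscle,
        "side": meta.side.value,
    }


def _meta_from_json(d: dict) -> ChannelMeta:
    try:
        return ChannelMeta(
            name=d["name"],
            kind=ChannelKind(d["kind"]),
            side=Side(d["side"]),
            muscle=d.get("muscle"),
        )
    except (KeyError, ValueError) as exc:
        raise MetadataError(f"bad column entry {d!r}: {exc}") from exc


def write_recording(
    rec: Recording, csv_path: str | Path, descriptor_path: str | Path
) -> None:
    """Write a recording as wide CSV file(s) plus a JSON descriptor.

    Channels are grouped by (rate_hz, t0_s); each group goes to its own CSV.
    The first group uses ``csv_path`` verbatim, further groups get a numeric
    suffix before the extension. Numeric content survives a round trip
    through :func:`read_recording` to better than 1e-6 relative.
    """
    csv_path = Path(csv_path)
    descriptor_path = Path(descriptor_path)

    groups: dict[tuple[float, float], _FileGroup] = {}
    for meta, sig in rec:
        key = (sig.rate_hz, sig.t0_s)
        if key not in groups:
            idx = len(groups)
            if idx == 0:
                path = csv_path
            else:
                path = csv_path.with_name(f"{csv_path.stem}_{idx}{csv_path.suffix}")
            groups[key] = _FileGroup(path=str(path), rate_hz=key[0], t0_s=key[1])
        groups[key].columns.append(meta)

    for (rate, t0), grp in groups.items():
        frame = pd.DataFrame(
            {m.name: rec.channels[m].samples for m in grp.columns}
        )
        frame.to_csv(grp.path, index=False, float_format="%.9g")

    descriptor = {
        "label": rec.label,
        "speed_kmh": rec.speed_kmh,
        "files": [
            {
                "path": Path(grp.path).name,
                "rate_hz": grp.rate_hz,
                "t0_s": grp.t0_s,
                "columns": [_meta_to_json(m) for m in grp.columns],
            }
            for grp in groups.values()
        ],
    }
    descriptor_path.write_text(json.dumps(descriptor, indent=2))


def read_recording(
    csv_path: str | Path, descriptor_path: str | Path
) -> Recording:
    """Load a recording from CSV(s) + descriptor written by :func:`write_recording`.

    ``csv_path`` anchors relative file paths in the descriptor (its parent
    directory is used); the descriptor's own ``files[].path`` entries select
    the actual CSV files.
    """
    csv_path = Path(csv_path)
    base = csv_path.parent
    try:
        descriptor = json.loads(Path(descriptor_path).read_text())
    except json.JSONDecodeError as exc:
        raise DescriptorMismatchError(f"descriptor is not valid JSON: {exc}") from exc

    channels: dict[ChannelMeta, SampledSignal] = {}
    for entry in descriptor.get("files", []):
        path = base / entry["path"]
        if not path.exists():
            # descriptor may carry an absolute or csv_path-identical path
            alt = Path(entry["path"])
            path = alt if alt.exists() else csv_path
        try:
            frame = pd.read_csv(path)
        except ValueError as exc:
            raise SignalParseError(f"cannot parse {path}: {exc}") from exc
        rate = float(entry["rate_hz"])
        t0 = float(entry.get("t0_s", 0.0))
        for col in entry["columns"]:
            meta = _meta_from_json(col)
            if meta.name not in frame.columns:
                raise DescriptorMismatchError(
                    f"descriptor column {meta.name!r} absent from {path.name}"
                )
            raw = frame[meta.name]
            values = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=np.float64)
            bad = np.flatnonzero(np.isnan(values) & ~raw.isna().to_numpy())
            if bad.size:
                raise SignalParseError(
                    f"non-numeric value in column {meta.name!r} at row {bad[0]}"
                )
            if np.isnan(values).any():
                raise SignalParseError(
                    f"missing value in column {meta.name!r} at row "
                    f"{int(np.flatnonzero(np.isnan(values))[0])}"
                )
            channels[meta] = SampledSignal(values, rate, t0)

    if not channels:
        raise DescriptorMismatchError("descriptor declares no channels")
    return Recording(
        channels,
        label=descriptor.get("label", ""),
        speed_kmh=descriptor.get("speed_kmh"),
    )


def align_timebases(rec: Recording) -> Recording:
    """Trim all channels to their maximal common time interval.

    Trimming keeps, per channel, the samples whose times fall inside
    [max t0, min end); with mixed rates one trim can expose a slightly
    smaller interval, so the trim is repeated until nothing changes —
    this makes the operation exactly idempotent. Raises
    :class:`AlignmentError` when the channels share no overlap.
    """
    chans = dict(rec.channels)
    eps = 1e-9
    while True:
        start = max(sig.t0_s for sig in chans.values())
        end = min(sig.end_s for sig in chans.values())
        if end - start <= eps:
            raise AlignmentError(
                f"channels share no common interval "
                f"(start {start:.4f} s >= end {end:.4f} s)"
            )
        changed = False
        nxt: dict[ChannelMeta, SampledSignal] = {}
        for meta, sig in chans.items():
            i0 = max(int(math.ceil((start - sig.t0_s) * sig.rate_hz - eps)), 0)
            i1 = min(
                int(math.ceil((end - sig.t0_s) * sig.rate_hz - eps)),
                len(sig.samples),
            )
            if i1 <= i0:
                raise AlignmentError(
                    f"channel {meta.name!r} empty after trimming to common interval"
                )
            if i0 == 0 and i1 == len(sig.samples):
                nxt[meta] = sig
            else:
                changed = True
                nxt[meta] = SampledSignal(
                    sig.samples[i0:i1],
                    sig.rate_hz,
                    sig.t0_s + i0 / sig.rate_hz,
                )
        chans = nxt
        if not changed:
            break
    return Recording(chans, label=rec.label, speed_kmh=rec.speed_kmh)
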