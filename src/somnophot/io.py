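"""Recording container, event log, and standard-format export.

The native on-disk format is a single HDF5 file::

    /channels/<name>   dataset (float64)   attrs: rate, units, kind
    /events/onset, /events/duration, /events/kind, /events/attributes
    root attrs: schema_version, start_time, metadata (JSON)

Times are seconds from recording start (0-based); every interval is
half-open ``[onset, onset + duration)``.  EEG/EMG can additionally be
exported to EDF (the polysomnography interchange standard) with the
documented 16-bit quantization loss; events export to plain CSV.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Channel",
    "Event",
    "EventSet",
    "Recording",
    "SchemaError",
    "read_recording",
    "write_recording",
    "export_edf",
    "events_to_csv",
    "read_events_csv",
    "load_config",
    "setup_logging",
]

SCHEMA_VERSION = 1

CHANNEL_KINDS = ("fluorescence", "eeg", "emg", "amperometric")
EVENT_KINDS = ("stim_blue", "stim_yellow", "transition", "substate_onset")

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A recording file or object violates the container schema."""


@dataclass
class Event:
    """A timestamped event: stimulation, state transition, or sub-state onset.

    ``attributes`` carries kind-specific detail, e.g. ``color`` for
    stimulations or ``from_state``/``to_state`` for transitions.
    """

    onset: float
    duration: float = 0.0
    kind: str = "stim_blue"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SchemaError(f"unknown event kind {self.kind!r}")
        if self.duration < 0:
            raise SchemaError(f"event duration must be >= 0, got {self.duration}")


class EventSet:
    """An onset-sorted collection of :class:`Event` records."""

    def __init__(self, events: Sequence[Event] = ()) -> None:
        self.events: list[Event] = sorted(events, key=lambda e: e.onset)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i: int) -> Event:
        return self.events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return self.to_dataframe().equals(other.to_dataframe())

    def add(self, event: Event) -> None:
        self.events.append(event)
        self.events.sort(key=lambda e: e.onset)

    def of_kind(self, *kinds: str) -> "EventSet":
        return EventSet([e for e in self.events if e.kind in kinds])

    def onsets(self, kind: str | None = None) -> np.ndarray:
        evs = self.events if kind is None else [e for e in self.events if e.kind == kind]
        return np.array([e.onset for e in evs], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "duration": [e.duration for e in self.events],
                "kind": [e.kind for e in self.events],
                "attributes": [json.dumps(e.attributes, sort_keys=True) for e in self.events],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventSet":
        events = [
            Event(
                onset=float(row.onset),
                duration=float(row.duration),
                kind=str(row.kind),
                attributes=json.loads(row.attributes) if isinstance(row.attributes, str) else {},
            )
            for row in df.itertuples()
        ]
        return cls(events)

    def validate(self, duration: float | None = None) -> None:
        onsets = self.onsets()
        if len(onsets) > 1 and np.any(np.diff(onsets) < 0):
            raise SchemaError("events: onsets not sorted ascending")
        for e in self.events:
            if e.duration < 0:
                raise SchemaError("events: negative duration")
            if duration is not None and not (0.0 <= e.onset <= duration):
                raise SchemaError(
                    f"events: onset {e.onset} outside recording span [0, {duration}]"
                )


@dataclass
class Channel:
    """One uniformly sampled channel."""

    samples: np.ndarray
    rate: float
    units: str = "a.u."
    kind: str = "fluorescence"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SchemaError(f"channel rate must be positive, got {self.rate}")
        if self.kind not in CHANNEL_KINDS:
            raise SchemaError(f"unknown channel kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass
class Recording:
    """Synchronized multichannel recording with an event log.

    All channels start at ``start_time`` (0 by convention); channels may
    have different rates (photometry at 1 kHz next to lactate at 1 Hz).
    """

    channels: dict[str, Channel]
    events: EventSet = field(default_factory=EventSet)
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        if not self.channels:
            return 0.0
        return max(ch.duration for ch in self.channels.values())

    def validate(self) -> None:
        if not self.channels:
            raise SchemaError("recording has no channels")
        for name, ch in self.channels.items():
            if ch.rate <= 0:
                raise SchemaError(f"channel {name!r}: non-positive rate")
            if not np.all(np.isfinite(ch.samples)):
                raise SchemaError(f"channel {name!r}: non-finite samples")
        self.events.validate(self.duration)


# ---------------------------------------------------------------------------
# native HDF5 container


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` to the native HDF5 container.

    Round trips are lossless to float64 precision; events and metadata
    are preserved exactly.
    """
    recording.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["start_time"] = recording.start_time
        f.attrs["metadata"] = json.dumps(recording.metadata, sort_keys=True)
        g = f.create_group("channels")
        for name, ch in recording.channels.items():
            d = g.create_dataset(name, data=ch.samples)
            d.attrs["rate"] = ch.rate
            d.attrs["units"] = ch.units
            d.attrs["kind"] = ch.kind
        ev = f.create_group("events")
        df = recording.events.to_dataframe()
        ev.create_dataset("onset", data=df["onset"].to_numpy(dtype=float))
        ev.create_dataset("duration", data=df["duration"].to_numpy(dtype=float))
        str_dt = h5py.string_dtype(encoding="utf-8")
        ev.create_dataset("kind", data=df["kind"].to_list(), dtype=str_dt)
        ev.create_dataset("attributes", data=df["attributes"].to_list(), dtype=str_dt)
    logger.info("wrote recording with %d channels to %s", len(recording.channels), path)
    return path


def read_recording(path: str | Path) -> Recording:
    """Read and validate a native container file."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version}")
        if "channels" not in f or len(f["channels"]) == 0:
            raise SchemaError("missing channel group")
        channels = {}
        for name, d in f["channels"].items():
            for attr in ("rate", "units", "kind"):
                if attr not in d.attrs:
                    raise SchemaError(f"channel {name!r}: missing attribute {attr!r}")
            channels[name] = Channel(
                samples=d[()],
                rate=float(d.attrs["rate"]),
                units=str(d.attrs["units"]),
                kind=str(d.attrs["kind"]),
            )
        ev = f["events"]
        n = len(ev["onset"])
        events = EventSet(
            [
                Event(
                    onset=float(ev["onset"][i]),
                    duration=float(ev["duration"][i]),
                    kind=ev["kind"][i].decode() if isinstance(ev["kind"][i], bytes) else str(ev["kind"][i]),
                    attributes=json.loads(ev["attributes"][i]),
                )
                for i in range(n)
            ]
        )
        rec = Recording(
            channels=channels,
            events=events,
            start_time=float(f.attrs["start_time"]),
            metadata=json.loads(f.attrs["metadata"]),
        )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# EDF export

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = f"{float(value):.{max(width - 6, 1)}g}" if not isinstance(value, str) else s[:width]
        s = s[:width]
    return s.ljust(width).encode("ascii")


def export_edf(recording: Recording, channels: Sequence[str], path: str | Path) -> Path:
    """Export EEG/EMG channels to EDF with 1-s data records.

    EDF stores 16-bit integers against a per-signal physical range, so
    re-imported samples differ from the originals by at most one
    quantization step ``(phys_max - phys_min) / 65535``.  All exported
    channels must share one integer sampling rate.
    """
    path = Path(path)
    chans = []
    for name in channels:
        if name not in recording.channels:
            raise SchemaError(f"channel {name!r} not in recording")
        ch = recording.channels[name]
        if ch.kind not in ("eeg", "emg"):
            raise SchemaError(f"channel {name!r}: EDF export supports eeg/emg, got {ch.kind!r}")
        chans.append((name, ch))
    rates = {ch.rate for _, ch in chans}
    if len(rates) != 1:
        raise SchemaError(f"EDF export requires one uniform rate, got {sorted(rates)}")
    rate = rates.pop()
    if abs(rate - round(rate)) > 1e-9:
        raise SchemaError(f"EDF export requires an integer rate, got {rate}")
    spr = int(round(rate))  # samples per 1-s record
    n_records = min(len(ch.samples) // spr for _, ch in chans)
    if n_records == 0:
        raise SchemaError("recording shorter than one EDF data record (1 s)")

    ns = len(chans)
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(str(recording.metadata.get("subject", "X")), 80)
    header += _edf_field("somnophot export", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (ns + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(ns, 4)

    phys: list[tuple[float, float]] = []
    for name, ch in chans:
        lo = float(np.min(ch.samples[: n_records * spr]))
        hi = float(np.max(ch.samples[: n_records * spr]))
        if hi <= lo:
            hi = lo + 1.0
        phys.append((lo, hi))

    def col(fn):
        return b"".join(fn(i, name, ch) for i, (name, ch) in enumerate(chans))

    header += col(lambda i, name, ch: _edf_field(name, 16))
    header += col(lambda i, name, ch: _edf_field("", 80))
    header += col(lambda i, name, ch: _edf_field(ch.units, 8))
    header += col(lambda i, name, ch: _edf_field(f"{phys[i][0]:.6g}"[:8], 8))
    header += col(lambda i, name, ch: _edf_field(f"{phys[i][1]:.6g}"[:8], 8))
    header += col(lambda i, name, ch: _edf_field(_EDF_DIG_MIN, 8))
    header += col(lambda i, name, ch: _edf_field(_EDF_DIG_MAX, 8))
    header += col(lambda i, name, ch: _edf_field("", 80))
    header += col(lambda i, name, ch: _edf_field(spr, 8))
    header += col(lambda i, name, ch: _edf_field("", 32))

    digital = []
    for i, (name, ch) in enumerate(chans):
        # header physical range is re-parsed from its 8-char ASCII form so the
        # stored scaling matches what a reader reconstructs
        lo = float(f"{phys[i][0]:.6g}"[:8])
        hi = float(f"{phys[i][1]:.6g}"[:8])
        x = np.clip(ch.samples[: n_records * spr], lo, hi)
        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (hi - lo)
        digital.append(np.round((x - lo) * scale + _EDF_DIG_MIN).astype("<i2"))

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            for d in digital:
                f.write(d[r * spr : (r + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# CSV event log, config, logging


def events_to_csv(eventset: EventSet, path: str | Path) -> Path:
    """Write events to CSV (columns onset, duration, kind, attributes-JSON)."""
    path = Path(path)
    eventset.to_dataframe().to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> EventSet:
    df = pd.read_csv(path, dtype={"attributes": str})
    if len(df) == 0:
        return EventSet()
    return EventSet.from_dataframe(df)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, Mapping):
        raise SchemaError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return dict(cfg)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
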