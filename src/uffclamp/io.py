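"""Data model and on-disk formats for force-clamp traces and event tables.

All quantities use a single global unit system: seconds, nanometers,
piconewtons, rates in s^-1.  Time coordinates are 0-based from the start of a
trace and intervals are half-open ``[start, end)``.

Traces are stored in HDF5 (one group per trace, arrays as datasets, scalar
metadata as attributes) because an hour of 250 kHz data is ~10^9 samples and
must be chunked/seekable.  Event tables and ground-truth tables are
tab-separated text with a leading format line so fixtures stay
human-inspectable.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"
_FORMAT_MAJOR = 1

EVENT_COLUMNS = [
    "start_s",
    "end_s",
    "duration_s",
    "force_pN",
    "direction",
    "molecule_id",
    "trace_id",
    "sigma_t_s",
]

DIRECTIONS = ("hindering", "assisting")


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class SchemaError(ValueError):
    """A file is structurally incompatible with the expected format."""


@dataclass
class InstrumentConfig:
    """Instrument operating point of the ultrafast force clamp.

    Parameters
    ----------
    applied_force:
        Magnitude of the clamped force on the dumbbell, pN (1.5-4.5 in the
        experiments emulated here).
    pretension:
        Constant pretension on the actin filament, pN.  Metadata only: the
        clamp distributes forces so pretension is unchanged when the applied
        force alternates.
    trap_stiffness:
        Optical trap stiffness, pN/nm.  Metadata only.
    excursion:
        Peak-to-peak travel of the triangle-wave filament motion, nm.
    drag_coefficient:
        Effective viscous drag of the bead-actin-bead dumbbell, pN*s/nm.
        Sets the unbound velocity ``applied_force / drag_coefficient``.
    response_time:
        Time constant of motion arrest when myosin binds, s.
    noise_sd:
        White (per-sample) measurement noise on position, nm.
    ou_noise_sd, ou_tau_s:
        Standard deviation (nm) and correlation time (s) of the low-pass
        Ornstein-Uhlenbeck position-noise term emulating Brownian dumbbell
        fluctuation under feedback.  Set to 0 for noise-free traces.
    force_noise_sd:
        White measurement noise on the force channels, pN.
    temperature_kT:
        Thermal energy, pN*nm.
    """

    applied_force: float = 3.0
    pretension: float = 4.5
    trap_stiffness: float = 0.07
    excursion: float = 200.0
    drag_coefficient: float = 4.5e-5
    response_time: float = 5e-5
    noise_sd: float = 1.0
    ou_noise_sd: float = 2.0
    ou_tau_s: float = 2.5e-4
    force_noise_sd: float = 0.05
    temperature_kT: float = 4.11

    def __post_init__(self) -> None:
        for name in (
            "applied_force",
            "pretension",
            "trap_stiffness",
            "excursion",
            "drag_coefficient",
            "response_time",
            "temperature_kT",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"InstrumentConfig.{name} must be > 0")
        for name in ("noise_sd", "ou_noise_sd", "ou_tau_s", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"InstrumentConfig.{name} must be >= 0")
        if self.applied_force > 10:
            raise ValidationError("applied_force must be <= 10 pN")

    @property
    def unbound_speed(self) -> float:
        """Unbound filament speed, nm/s."""
        return self.applied_force / self.drag_coefficient

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(**d)


@dataclass
class Trace:
    """Synchronized force-clamp time series.

    ``trap_pos_lead`` (the more highly loaded bead's trap, taken as the actin
    filament position proxy) and ``trap_pos_trail`` are in nm; forces in pN;
    ``pause_flag`` marks samples recorded while the feedback loop was paused.
    ``polarity`` (+1/-1) is the direction of the myosin working stroke along
    the position axis.
    """

    dt: float
    trap_pos_lead: np.ndarray
    trap_pos_trail: np.ndarray
    force_lead: np.ndarray
    force_trail: np.ndarray
    pause_flag: np.ndarray
    meta: InstrumentConfig = field(default_factory=InstrumentConfig)
    molecule_id: str = "mol0"
    trace_id: str = "trace0"
    polarity: int = 1

    def __post_init__(self) -> None:
        self.trap_pos_lead = np.asarray(self.trap_pos_lead, dtype=float)
        self.trap_pos_trail = np.asarray(self.trap_pos_trail, dtype=float)
        self.force_lead = np.asarray(self.force_lead, dtype=float)
        self.force_trail = np.asarray(self.force_trail, dtype=float)
        self.pause_flag = np.asarray(self.pause_flag, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")
        n = len(self.trap_pos_lead)
        if n < 2:
            raise ValidationError("trace must have at least 2 samples")
        for name in ("trap_pos_trail", "force_lead", "force_trail", "pause_flag"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"array length mismatch in {name}")
        for name in ("trap_pos_lead", "trap_pos_trail", "force_lead", "force_trail"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in {name}")
        if self.polarity not in (-1, 1):
            raise ValidationError("polarity must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return len(self.trap_pos_lead)

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class GroundTruthEvent:
    """Truth channel for one simulated actomyosin interaction.

    ``state_path`` is the ordered list of (state name, absolute entry time)
    pairs; ``stroke_time_s`` is the absolute time of the first working-stroke
    transition, or None if the molecule detached pre-stroke.
    """

    start_s: float
    end_s: float
    state_path: list  # [(state_name, entry_time_s), ...]
    stroke_time_s: float | None = None
    detached_prestroke: bool = False
    direction: str = "hindering"
    force_pN: float = 0.0
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValidationError("ground-truth event must have end > start")
        times = [t for _, t in self.state_path]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("state entry times must be strictly increasing")
        if self.stroke_time_s is not None and not (
            self.start_s <= self.stroke_time_s <= self.end_s
        ):
            raise ValidationError("stroke_time_s outside [start, end]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# Trace container (HDF5)
# ---------------------------------------------------------------------------

_TRACE_ARRAYS = ("trap_pos_lead", "trap_pos_trail", "force_lead", "force_trail")


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a validated trace to an HDF5 container (round-trips bit-exactly)."""
    trace.validate()
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "uffclamp-trace"
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("trace")
        for name in _TRACE_ARRAYS:
            g.create_dataset(name, data=getattr(trace, name), chunks=True)
        g.create_dataset("pause_flag", data=trace.pause_flag, chunks=True)
        g.attrs["dt"] = trace.dt
        g.attrs["molecule_id"] = trace.molecule_id
        g.attrs["trace_id"] = trace.trace_id
        g.attrs["polarity"] = trace.polarity
        g.attrs["instrument"] = json.dumps(trace.meta.to_dict())


def read_trace(path: str | Path) -> Trace:
    with h5py.File(path, "r") as f:
        _check_version(f.attrs.get("format_version", ""), path)
        g = f["trace"]
        arrays = {name: g[name][:] for name in _TRACE_ARRAYS}
        return Trace(
            dt=float(g.attrs["dt"]),
            pause_flag=g["pause_flag"][:],
            meta=InstrumentConfig.from_dict(json.loads(g.attrs["instrument"])),
            molecule_id=str(g.attrs["molecule_id"]),
            trace_id=str(g.attrs["trace_id"]),
            polarity=int(g.attrs["polarity"]),
            **arrays,
        )


def _check_version(version: str, path) -> None:
    try:
        major = int(str(version).split(".")[0])
    except (ValueError, IndexError):
        raise SchemaError(f"{path}: missing or malformed format_version") from None
    if major != _FORMAT_MAJOR:
        raise SchemaError(
            f"{path}: unsupported major format version {version!r} "
            f"(reader supports {_FORMAT_MAJOR}.x)"
        )


# ---------------------------------------------------------------------------
# Event tables (TSV)
# ---------------------------------------------------------------------------

_EVENTS_MAGIC = "# uffclamp-events"
_TRUTH_MAGIC = "# uffclamp-truth"


def validate_events(table: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table schema and invariants; returns the table."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table missing required columns: {missing}")
    if len(table):
        if not (table["end_s"] > table["start_s"]).all():
            raise ValidationError("event with end_s <= start_s")
        if not (table["duration_s"] > 0).all():
            raise ValidationError("non-positive event duration")
        bad = set(table["direction"].unique()) - set(DIRECTIONS)
        if bad:
            raise ValidationError(f"unknown event direction(s): {sorted(bad)}")
    return table


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    validate_events(table)
    with open(path, "w") as f:
        f.write(f"{_EVENTS_MAGIC} v{FORMAT_VERSION}\n")
        table.to_csv(f, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    with open(path) as f:
        first = f.readline()
        if not first.startswith(_EVENTS_MAGIC):
            raise SchemaError(f"{path}: not an uffclamp event table")
        _check_version(first.rsplit("v", 1)[-1].strip(), path)
        table = pd.read_csv(f, sep="\t")
    if len(table) and "direction" in table.columns:
        table["direction"] = table["direction"].astype(str)
    return validate_events(table)


def events_dataframe(records: Sequence[dict]) -> pd.DataFrame:
    """Build a validated event table from per-event dicts."""
    if not records:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return validate_events(pd.DataFrame.from_records(list(records)))


# ---------------------------------------------------------------------------
# Ground truth tables (TSV; state path serialized as JSON)
# ---------------------------------------------------------------------------


def write_truth(events: Sequence[GroundTruthEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "stroke_time_s": "" if ev.stroke_time_s is None else ev.stroke_time_s,
                "detached_prestroke": int(ev.detached_prestroke),
                "direction": ev.direction,
                "force_pN": ev.force_pN,
                "truncated": int(ev.truncated),
                "state_path": json.dumps(ev.state_path),
            }
        )
    with open(path, "w") as f:
        f.write(f"{_TRUTH_MAGIC} v{FORMAT_VERSION}\n")
        pd.DataFrame(
            rows,
            columns=[
                "start_s",
                "end_s",
                "stroke_time_s",
                "detached_prestroke",
                "direction",
                "force_pN",
                "truncated",
                "state_path",
            ],
        ).to_csv(f, sep="\t", index=False)


def read_truth(path: str | Path) -> list[GroundTruthEvent]:
    with open(path) as f:
        first = f.readline()
        if not first.startswith(_TRUTH_MAGIC):
            raise SchemaError(f"{path}: not an uffclamp ground-truth table")
        _check_version(first.rsplit("v", 1)[-1].strip(), path)
        table = pd.read_csv(f, sep="\t")
    out = []
    for _, row in table.iterrows():
        stroke = row["stroke_time_s"]
        out.append(
            GroundTruthEvent(
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                state_path=[(str(s), float(t)) for s, t in json.loads(row["state_path"])],
                stroke_time_s=None if pd.isna(stroke) or stroke == "" else float(stroke),
                detached_prestroke=bool(row["detached_prestroke"]),
                direction=str(row["direction"]),
                force_pN=float(row["force_pN"]),
                truncated=bool(row["truncated"]),
            )
        )
    return out
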