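"""In-memory study data model.

A :class:`Study` is the root container of an analysis: named subjects (each
holding one or more modality substructures plus the original raw files,
byte-exact), an ordered workflow of configured plugin stages, a snapshot of
every referenced plugin's source code, a lock flag and an append-only
provenance log.  Every processing stage reads and writes this structure and
nothing else, which is what makes a study self-contained and shareable.

Time is modelled as uniformly sampled: a channel stores a sample rate and a
start time, and the time of sample ``i`` (0-based) is
``start_time + i / sample_rate``.  All windows elsewhere in the package are
half-open ``[start, end)`` seconds.  Missing samples are represented by NaN;
file readers map dialect-specific missing codes onto it.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

import numpy as np
import pandas as pd


class LockedStudyError(RuntimeError):
    """Raised when a mutating operation is attempted on a locked study."""


# ---------------------------------------------------------------------------
# channels and events
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class TimeSeriesChannel:
    """A uniformly sampled signal with NaN as the missing-value marker."""

    name: str
    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def end_time(self) -> float:
        """End of the recording (half-open): time just past the last sample."""
        return self.start_time + self.n_samples / self.sample_rate

    def time_of(self, i: int) -> float:
        return self.start_time + i / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def with_values(self, values: np.ndarray) -> "TimeSeriesChannel":
        return TimeSeriesChannel(
            name=self.name,
            sample_rate=self.sample_rate,
            values=np.asarray(values, dtype=float),
            start_time=self.start_time,
            units=self.units,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeriesChannel):
            return NotImplemented
        return (
            self.name == other.name
            and self.sample_rate == other.sample_rate
            and self.start_time == other.start_time
            and self.units == other.units
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def to_dict(self) -> dict:
        return {
            "__type__": "TimeSeriesChannel",
            "name": self.name,
            "sample_rate": self.sample_rate,
            "start_time": self.start_time,
            "units": self.units,
            "values": _floats_to_jsonable(self.values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimeSeriesChannel":
        return cls(
            name=d["name"],
            sample_rate=d["sample_rate"],
            values=_jsonable_to_floats(d["values"]),
            start_time=d["start_time"],
            units=d["units"],
        )


@dataclass
class Event:
    """A condition/trigger label at a time (seconds from the channel origin)."""

    name: str
    time: float

    def to_dict(self) -> dict:
        return {"name": self.name, "time": self.time}


@dataclass
class EventList:
    """Events sorted ascending by time; ties keep insertion order."""

    events: list[Event] = field(default_factory=list)

    def add(self, event: Event) -> None:
        # stable sort keeps insertion order among equal times
        self.events.append(event)
        self.events.sort(key=lambda e: e.time)

    def extend(self, events: Iterable[Event]) -> None:
        self.events.extend(events)
        self.events.sort(key=lambda e: e.time)

    def is_sorted(self) -> bool:
        times = [e.time for e in self.events]
        return all(a <= b for a, b in zip(times, times[1:]))

    def names(self) -> list[str]:
        return [e.name for e in self.events]

    def times(self) -> np.ndarray:
        return np.asarray([e.time for e in self.events], dtype=float)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def to_dict(self) -> dict:
        return {"__type__": "EventList", "events": [e.to_dict() for e in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "EventList":
        return cls(events=[Event(e["name"], e["time"]) for e in d["events"]])


# ---------------------------------------------------------------------------
# derived (event-related) results
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ConditionEpochs:
    """Baseline-corrected trials of one condition: a trials x samples matrix,
    the trial onset times, and one scalar measure value per trial."""

    matrix: np.ndarray
    onsets: np.ndarray
    trialvalues: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConditionEpochs):
            return NotImplemented
        return (
            np.array_equal(self.matrix, other.matrix, equal_nan=True)
            and np.array_equal(self.onsets, other.onsets, equal_nan=True)
            and np.array_equal(self.trialvalues, other.trialvalues, equal_nan=True)
        )

    def to_dict(self) -> dict:
        return {
            "matrix": [_floats_to_jsonable(row) for row in np.atleast_2d(self.matrix)]
            if self.matrix.size
            else [],
            "n_trial_samples": int(self.matrix.shape[1]) if self.matrix.ndim == 2 else 0,
            "onsets": _floats_to_jsonable(self.onsets),
            "trialvalues": _floats_to_jsonable(self.trialvalues),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionEpochs":
        n_cols = d.get("n_trial_samples", 0)
        if d["matrix"]:
            matrix = np.asarray([_jsonable_to_floats(r) for r in d["matrix"]])
        else:
            matrix = np.empty((0, n_cols))
        return cls(
            matrix=matrix,
            onsets=_jsonable_to_floats(d["onsets"]),
            trialvalues=_jsonable_to_floats(d["trialvalues"]),
        )


@dataclass(eq=False)
class EventRelatedData:
    """Per-condition epoch data produced by event-related extraction."""

    conditions: dict[str, ConditionEpochs]
    sample_rate: float
    trial_window: tuple[float, float]
    measure: str

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventRelatedData):
            return NotImplemented
        return (
            self.sample_rate == other.sample_rate
            and tuple(self.trial_window) == tuple(other.trial_window)
            and self.measure == other.measure
            and self.conditions == other.conditions
        )

    def to_dict(self) -> dict:
        return {
            "__type__": "EventRelatedData",
            "sample_rate": self.sample_rate,
            "trial_window": list(self.trial_window),
            "measure": self.measure,
            "conditions": {k: v.to_dict() for k, v in self.conditions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventRelatedData":
        return cls(
            conditions={k: ConditionEpochs.from_dict(v) for k, v in d["conditions"].items()},
            sample_rate=d["sample_rate"],
            trial_window=tuple(d["trial_window"]),
            measure=d["measure"],
        )


@dataclass(eq=False)
class ConditionCurves:
    """Pointwise condition averages with a confidence band."""

    times: np.ndarray
    curves: dict[str, dict[str, np.ndarray]]  # condition -> {mean, lo, hi}
    level: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConditionCurves):
            return NotImplemented
        if self.level != other.level or set(self.curves) != set(other.curves):
            return False
        if not np.array_equal(self.times, other.times, equal_nan=True):
            return False
        for cond, c in self.curves.items():
            o = other.curves[cond]
            for k in ("mean", "lo", "hi"):
                if not np.array_equal(c[k], o[k], equal_nan=True):
                    return False
        return True

    def to_dict(self) -> dict:
        return {
            "__type__": "ConditionCurves",
            "times": _floats_to_jsonable(self.times),
            "level": self.level,
            "curves": {
                cond: {k: _floats_to_jsonable(v) for k, v in c.items()}
                for cond, c in self.curves.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionCurves":
        return cls(
            times=_jsonable_to_floats(d["times"]),
            level=d["level"],
            curves={
                cond: {k: _jsonable_to_floats(v) for k, v in c.items()}
                for cond, c in d["curves"].items()
            },
        )


TRIAL_TABLE_COLUMNS = ["subject", "condition", "trial", "measure", "value"]


@dataclass(eq=False)
class TrialMeasureTable:
    """Long-format table: one row per (subject, condition, trial, measure)."""

    df: pd.DataFrame

    @classmethod
    def from_rows(cls, rows: list[tuple]) -> "TrialMeasureTable":
        df = pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
        return cls(cls._normalize(df))

    @staticmethod
    def _normalize(df: pd.DataFrame) -> pd.DataFrame:
        df = df.reset_index(drop=True)
        return df.astype(
            {"subject": str, "condition": str, "trial": "int64", "measure": str, "value": float}
        )

    def concat(self, other: "TrialMeasureTable") -> "TrialMeasureTable":
        return TrialMeasureTable(
            self._normalize(pd.concat([self.df, other.df], ignore_index=True))
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NaN")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialMeasureTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)

    def to_dict(self) -> dict:
        return {
            "__type__": "TrialMeasureTable",
            "rows": [
                [r.subject, r.condition, int(r.trial), r.measure, _float_to_jsonable(r.value)]
                for r in self.df.itertuples()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeasureTable":
        rows = [
            (s, c, t, m, math.nan if v is None else float(v)) for s, c, t, m, v in d["rows"]
        ]
        df = pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
        return cls(cls._normalize(df))


_DERIVED_TYPES = {
    "TimeSeriesChannel": TimeSeriesChannel,
    "EventList": EventList,
    "EventRelatedData": EventRelatedData,
    "ConditionCurves": ConditionCurves,
    "TrialMeasureTable": TrialMeasureTable,
}


def derived_from_dict(d: Any) -> Any:
    """Reconstruct a derived-data object from its tagged dict form."""
    if isinstance(d, dict) and "__type__" in d:
        return _DERIVED_TYPES[d["__type__"]].from_dict(d)
    return d


# ---------------------------------------------------------------------------
# subjects and the study root
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Modality:
    """One methodology's data for a subject: channels, events, derived results.

    All channels in a modality share the same sampling rate and time origin.
    """

    channels: dict[str, TimeSeriesChannel] = field(default_factory=dict)
    events: EventList = field(default_factory=EventList)
    derived: dict[str, Any] = field(default_factory=dict)

    @property
    def sample_rate(self) -> float | None:
        for ch in self.channels.values():
            return ch.sample_rate
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Modality):
            return NotImplemented
        return (
            self.channels == other.channels
            and self.events == other.events
            and set(self.derived) == set(other.derived)
            and all(self.derived[k] == other.derived[k] for k in self.derived)
        )

    def to_dict(self) -> dict:
        return {
            "channels": {k: v.to_dict() for k, v in self.channels.items()},
            "events": self.events.to_dict(),
            "derived": {
                k: (v.to_dict() if hasattr(v, "to_dict") else v)
                for k, v in self.derived.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Modality":
        return cls(
            channels={k: TimeSeriesChannel.from_dict(v) for k, v in d["channels"].items()},
            events=EventList.from_dict(d["events"]),
            derived={k: derived_from_dict(v) for k, v in d["derived"].items()},
        )


@dataclass(eq=False)
class Subject:
    """A named unit of data: zero or more modality substructures plus the
    original raw files, kept byte-exact for extraction and bundle round-trips.
    """

    name: str
    substructures: dict[str, Modality] = field(default_factory=dict)
    raw_files: dict[str, bytes] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Subject):
            return NotImplemented
        return (
            self.name == other.name
            and self.substructures == other.substructures
            and self.raw_files == other.raw_files
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "substructures": {k: v.to_dict() for k, v in self.substructures.items()},
            "raw_files": sorted(self.raw_files),
        }


@dataclass
class PluginInstance:
    """A configured workflow stage: plugin id, named settings set, settings
    mapping and a reference into the study's plugin source snapshots."""

    plugin_id: str
    settings_name: str = "default"
    settings: dict[str, Any] = field(default_factory=dict)
    source_ref: str | None = None

    def to_dict(self) -> dict:
        return {
            "plugin_id": self.plugin_id,
            "settings_name": self.settings_name,
            "settings": _jsonable_settings(self.settings),
            "source_ref": self.source_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PluginInstance":
        return cls(
            plugin_id=d["plugin_id"],
            settings_name=d["settings_name"],
            settings=dict(d["settings"]),
            source_ref=d.get("source_ref"),
        )


@dataclass
class ProvenanceRecord:
    """Append-only record of one plugin execution."""

    timestamp: str
    plugin_id: str
    settings_hash: str
    subjects: list[str]
    engine_version: str
    input_hash: str
    output_hash: str

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "plugin_id": self.plugin_id,
            "settings_hash": self.settings_hash,
            "subjects": list(self.subjects),
            "engine_version": self.engine_version,
            "input_hash": self.input_hash,
            "output_hash": self.output_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProvenanceRecord":
        return cls(**d)


@dataclass(eq=False)
class Study:
    """Root container of an analysis (subjects + workflow + plugin sources).

    Mutating methods raise :class:`LockedStudyError` once the study is locked.
    """

    name: str
    uwid: str | None = None
    locked: bool = False
    engine_version: str = ""
    subjects: list[Subject] = field(default_factory=list)
    workflow: list[PluginInstance] = field(default_factory=list)
    plugin_sources: dict[str, str] = field(default_factory=dict)
    provenance: list[ProvenanceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.engine_version:
            from . import __version__

            self.engine_version = __version__

    # -- mutation guards ----------------------------------------------------

    def check_unlocked(self) -> None:
        if self.locked:
            raise LockedStudyError(f"study {self.name!r} is locked; mutation rejected")

    def add_subject(self, subject: Subject) -> Subject:
        self.check_unlocked()
        if any(s.name == subject.name for s in self.subjects):
            raise ValueError(f"duplicate subject name {subject.name!r}")
        self.subjects.append(subject)
        return subject

    def subject(self, name: str) -> Subject:
        for s in self.subjects:
            if s.name == name:
                return s
        raise KeyError(name)

    def append_stage(self, instance: PluginInstance) -> None:
        self.check_unlocked()
        self.workflow.append(instance)

    def set_stage_settings(self, index: int, settings: dict[str, Any]) -> None:
        self.check_unlocked()
        self.workflow[index].settings = dict(settings)

    # -- equality and serialization -----------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Study):
            return NotImplemented
        return (
            self.name == other.name
            and self.uwid == other.uwid
            and self.locked == other.locked
            and self.engine_version == other.engine_version
            and self.subjects == other.subjects
            and [w.to_dict() for w in self.workflow] == [w.to_dict() for w in other.workflow]
            and self.plugin_sources == other.plugin_sources
            and [p.to_dict() for p in self.provenance]
            == [p.to_dict() for p in other.provenance]
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "uwid": self.uwid,
            "locked": self.locked,
            "engine_version": self.engine_version,
            "subjects": [s.to_dict() for s in self.subjects],
            "workflow": [w.to_dict() for w in self.workflow],
            "plugin_ids": sorted(self.plugin_sources),
            "provenance": [p.to_dict() for p in self.provenance],
        }


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_study(study: Study) -> list[str]:
    """Check every structural invariant; return violation descriptions.

    Never mutates and never raises: an empty list means the study is
    well-formed.  The lock flag is orthogonal to well-formedness.
    """
    violations: list[str] = []
    seen_names: set[str] = set()
    for subject in study.subjects:
        if subject.name in seen_names:
            violations.append(f"duplicate subject name {subject.name!r}")
        seen_names.add(subject.name)
        for mod_name, mod in subject.substructures.items():
            where = f"subject {subject.name!r} modality {mod_name!r}"
            rates = {ch.sample_rate for ch in mod.channels.values()}
            if len(rates) > 1:
                violations.append(f"{where}: channels disagree on sample rate ({sorted(rates)})")
            origins = {ch.start_time for ch in mod.channels.values()}
            if len(origins) > 1:
                violations.append(f"{where}: channels disagree on time origin ({sorted(origins)})")
            if not mod.events.is_sorted():
                violations.append(f"{where}: event list is not sorted by time")
            if mod.channels:
                start = min(ch.start_time for ch in mod.channels.values())
                end = max(ch.end_time for ch in mod.channels.values())
                for ev in mod.events:
                    if not (start <= ev.time <= end):
                        violations.append(
                            f"{where}: event {ev.name!r} at {ev.time} s outside recording "
                            f"[{start}, {end}]"
                        )
    for i, inst in enumerate(study.workflow):
        if inst.source_ref is not None and inst.source_ref not in study.plugin_sources:
            violations.append(
                f"workflow stage {i} ({inst.plugin_id}): source_ref {inst.source_ref!r} "
                "missing from plugin_sources"
            )
    return violations


# ---------------------------------------------------------------------------
# canonical hashing helpers
# ---------------------------------------------------------------------------


def _float_to_jsonable(v: float) -> float | None:
    v = float(v)
    return None if math.isnan(v) else v


def _floats_to_jsonable(a: np.ndarray) -> list:
    return [_float_to_jsonable(v) for v in np.asarray(a, dtype=float).ravel()]


def _jsonable_to_floats(vals: list) -> np.ndarray:
    return np.asarray([math.nan if v is None else float(v) for v in vals], dtype=float)


def _jsonable_settings(settings: dict) -> dict:
    out = {}
    for k, v in settings.items():
        if isinstance(v, float) and math.isnan(v):
            out[k] = None
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


def canonical_json(obj: Any) -> str:
    """Deterministic JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False)


def content_hash(obj: Any) -> str:
    """SHA-256 hex digest of an object's canonical JSON form."""
    return hashlib.sha256(canonical_json(obj).encode("utf-8")).hexdigest()


def derived_hash(study: Study) -> str:
    """Hash of every subject's derived results (the reproducibility contract:
    identical inputs, workflow and seed must reproduce this exactly)."""
    payload = {
        s.name: {
            m: {k: (v.to_dict() if hasattr(v, "to_dict") else v) for k, v in mod.derived.items()}
            for m, mod in s.substructures.items()
        }
        for s in study.subjects
    }
    return content_hash(payload)


def _channel_fingerprint(ch: TimeSeriesChannel) -> dict:
    values = np.ascontiguousarray(ch.values, dtype=float)
    return {
        "name": ch.name,
        "sample_rate": ch.sample_rate,
        "start_time": ch.start_time,
        "units": ch.units,
        "sha256": hashlib.sha256(values.tobytes() + str(values.shape).encode()).hexdigest(),
    }


def modality_state(study: Study, subject_names: list[str]) -> dict:
    """Deterministic snapshot of the selected subjects' modality contents
    (channels fingerprinted by their raw bytes; cheap enough to take before
    and after every stage for provenance)."""
    return {
        s.name: {
            m: {
                "channels": {k: _channel_fingerprint(ch) for k, ch in mod.channels.items()},
                "events": mod.events.to_dict(),
                "derived": {
                    k: content_hash(v.to_dict() if hasattr(v, "to_dict") else v)
                    for k, v in mod.derived.items()
                },
            }
            for m, mod in s.substructures.items()
        }
        for s in study.subjects
        if s.name in subject_names
    }
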