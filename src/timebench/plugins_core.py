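"""Core processing stages for event-related time-series analysis.

The shipped pipeline mirrors a standard event-related pupillometry
preprocessing chain:

1. ``core/read_file`` — flexible columnar text reader (one channel per mapped
   column, events from a label column);
2. ``core/modify_events`` — pattern-based event renaming, used to group raw
   stimulus triggers into conditions;
3. ``core/interpolate_gaps`` — fill short missing-data runs (blink gaps) by
   nearest/linear/cubic interpolation, with optional jump and range guards;
4. ``core/filter_moving_average`` — zero-phase sliding-window mean/median
   filter with shrinking windows at the edges;
5. ``core/event_related_extraction`` — epoch the signal around condition
   events, baseline-correct, compute per-trial scalar measures and
   per-condition average curves with confidence bands.

Each stage exists both as a pure function on the data model (testable in
isolation) and as a registered plugin wrapping it.
"""

from __future__ import annotations

import fnmatch
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate as _sp_interpolate
from scipy import stats as _sp_stats

from .model import (
    ConditionCurves,
    ConditionEpochs,
    Event,
    EventList,
    EventRelatedData,
    Modality,
    Study,
    Subject,
    TimeSeriesChannel,
    TrialMeasureTable,
)
from .plugin_api import PluginSpec, SettingSpec, default_registry

__all__ = [
    "ColumnMap",
    "read_columnar_file",
    "modify_events",
    "interpolate_gaps",
    "moving_filter",
    "extract_event_related",
    "EpochExtraction",
    "summarize_per_subject",
    "plot_condition_curves",
]


# ---------------------------------------------------------------------------
# stage 1: columnar file reader
# ---------------------------------------------------------------------------


@dataclass
class ColumnMap:
    """How to interpret a columnar eyetracker export.

    ``channels`` maps file column names to channel names; cells equal to one
    of the column's ``missing_codes`` become NaN.  Rows with a non-empty
    ``event_column`` cell yield an event named by that cell at the row's
    time.  ``sample_rate`` may be declared or inferred from timestamp deltas
    (validated within ``rate_tolerance`` relative deviation).
    """

    timestamp_column: str
    channels: dict[str, str]
    event_column: str | None = None
    timestamp_unit: str = "ms"  # "ms" or "s"
    missing_codes: dict[str, list[str]] = field(default_factory=dict)
    sample_rate: float | None = None
    rate_tolerance: float = 0.01
    separator: str = "\t"

    def __post_init__(self) -> None:
        if self.timestamp_column in self.channels:
            raise ValueError("timestamp column cannot also be a data column")
        if self.timestamp_unit not in ("ms", "s"):
            raise ValueError(f"unknown timestamp unit {self.timestamp_unit!r}")


def read_columnar_file(text: str, cmap: ColumnMap) -> Modality:
    """Parse a header-and-rows text export into a modality."""
    df = pd.read_csv(
        io.StringIO(text), sep=cmap.separator, dtype=str, keep_default_na=False
    )
    for col in [cmap.timestamp_column, *cmap.channels]:
        if col not in df.columns:
            raise ValueError(f"mapped column {col!r} absent from file header")
    if cmap.event_column is not None and cmap.event_column not in df.columns:
        raise ValueError(f"event column {cmap.event_column!r} absent from file header")

    try:
        t_raw = df[cmap.timestamp_column].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"unparseable timestamp: {exc}") from None
    times = t_raw / 1000.0 if cmap.timestamp_unit == "ms" else t_raw

    if len(times) >= 2:
        dt = np.diff(times)
        mean_dt = float(np.mean(dt))
        if mean_dt <= 0:
            raise ValueError("timestamps are not strictly increasing")
        inferred = 1.0 / mean_dt
        if np.any(np.abs(dt - mean_dt) > cmap.rate_tolerance * mean_dt):
            raise ValueError(
                "timestamp spacing is not uniform within tolerance "
                f"(mean dt {mean_dt:.6g} s)"
            )
        rate = cmap.sample_rate if cmap.sample_rate is not None else inferred
        if abs(inferred - rate) > cmap.rate_tolerance * rate:
            raise ValueError(
                f"declared sample rate {rate} Hz deviates from inferred "
                f"{inferred:.6g} Hz beyond tolerance"
            )
    else:
        rate = cmap.sample_rate if cmap.sample_rate is not None else 1.0

    start = float(times[0]) if len(times) else 0.0
    mod = Modality()
    for col, ch_name in cmap.channels.items():
        raw = df[col].to_numpy()
        codes = set(cmap.missing_codes.get(col, []))
        vals = np.array(
            [np.nan if (c in codes or c == "") else float(c) for c in raw], dtype=float
        )
        mod.channels[ch_name] = TimeSeriesChannel(
            name=ch_name, sample_rate=float(rate), values=vals, start_time=start
        )
    if cmap.event_column is not None and len(df):
        labels = df[cmap.event_column].to_numpy()
        mod.events.extend(
            Event(name=str(lab), time=float(times[i]))
            for i, lab in enumerate(labels)
            if str(lab) != ""
        )
    return mod


# ---------------------------------------------------------------------------
# stage 2: event modification
# ---------------------------------------------------------------------------


def modify_events(
    events: EventList, rules: Sequence[tuple[str, str]]
) -> EventList:
    """Rename events by the first matching rule (literal or shell-style
    wildcard pattern); unmatched events pass through; times and count are
    preserved."""
    out = []
    for ev in events:
        name = ev.name
        for pattern, new_name in rules:
            if fnmatch.fnmatchcase(ev.name, pattern):
                name = new_name
                break
        out.append(Event(name=name, time=ev.time))
    return EventList(events=out)


# ---------------------------------------------------------------------------
# stage 3: gap interpolation
# ---------------------------------------------------------------------------


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) pairs (half-open) of maximal True runs."""
    runs = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(
    ch: TimeSeriesChannel,
    max_gap: int,
    method: str = "linear",
    max_jump: float | None = None,
    valid_range: tuple[float, float] | None = None,
) -> TimeSeriesChannel:
    """Fill short missing-data runs (blink gaps) in a channel.

    A gap is filled iff its length is strictly smaller than ``max_gap``
    samples, it has valid samples on both sides (edge gaps are never
    filled), the flank jump does not exceed ``max_jump`` (if set), and every
    inserted value lies inside ``valid_range`` (if set).  Originally valid
    samples are never modified.
    """
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")
    if method not in ("nearest", "linear", "cubic"):
        raise ValueError(f"invalid interpolation method {method!r}")
    if valid_range is not None and valid_range[0] > valid_range[1]:
        raise ValueError(f"valid_range lower bound exceeds upper: {valid_range}")

    v = ch.values
    missing = np.isnan(v)
    if not missing.any():
        return ch.with_values(v.copy())
    valid_idx = np.flatnonzero(~missing)
    out = v.copy()
    if valid_idx.size < 2:
        return ch.with_values(out)
    if method == "cubic" and valid_idx.size < 4:
        raise ValueError("cubic interpolation needs at least 4 valid samples")
    interp = _sp_interpolate.interp1d(
        valid_idx, v[valid_idx], kind=method, assume_sorted=True, bounds_error=True
    )
    n = v.size
    for start, stop in _missing_runs(missing):
        length = stop - start
        if length >= max_gap:
            continue
        if start == 0 or stop == n:  # edge gap
            continue
        left, right = v[start - 1], v[stop]
        if max_jump is not None and abs(right - left) > max_jump:
            continue
        filled = interp(np.arange(start, stop))
        if valid_range is not None and (
            np.any(filled < valid_range[0]) or np.any(filled > valid_range[1])
        ):
            continue
        out[start:stop] = filled
    return ch.with_values(out)


# ---------------------------------------------------------------------------
# stage 4: zero-phase moving filter
# ---------------------------------------------------------------------------


def moving_filter(
    ch: TimeSeriesChannel, halfwidth: int, statistic: str = "mean"
) -> TimeSeriesChannel:
    """Sliding-window mean/median over ``[i-h, i+h]``, NaN-ignoring.

    The window is symmetric, so the filter is zero-phase; at the edges the
    window shrinks to the available samples (no padding, no truncation).  A
    window containing only missing values yields a missing output sample.
    """
    if halfwidth < 0:
        raise ValueError(f"halfwidth must be >= 0, got {halfwidth}")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown filter statistic {statistic!r}")
    s = pd.Series(ch.values)
    rolled = s.rolling(window=2 * halfwidth + 1, center=True, min_periods=1)
    out = rolled.mean() if statistic == "mean" else rolled.median()
    return ch.with_values(out.to_numpy())


# ---------------------------------------------------------------------------
# stage 5: event-related extraction
# ---------------------------------------------------------------------------

MEASURE_NAMES = (
    "mean",
    "median",
    "min",
    "max",
    "latency_to_min",
    "latency_to_max",
    "range",
)


def _measure(name: str, seg: np.ndarray, t0: float, sr: float) -> float:
    """One scalar measure of a trial segment; NaN if segment is all-missing.

    Latencies are seconds from the trial's event; ties take the earliest
    sample.
    """
    if seg.size == 0 or np.all(np.isnan(seg)):
        return float("nan")
    if name == "mean":
        return float(np.nanmean(seg))
    if name == "median":
        return float(np.nanmedian(seg))
    if name == "min":
        return float(np.nanmin(seg))
    if name == "max":
        return float(np.nanmax(seg))
    if name == "latency_to_min":
        return t0 + int(np.nanargmin(seg)) / sr
    if name == "latency_to_max":
        return t0 + int(np.nanargmax(seg)) / sr
    if name == "range":
        return float(np.nanmax(seg) - np.nanmin(seg))
    raise ValueError(f"unknown measure name {name!r}")


@dataclass
class EpochExtraction:
    """Result of event-related extraction for one subject/channel."""

    data: EventRelatedData
    table: TrialMeasureTable
    curves: ConditionCurves
    n_dropped: int


def extract_event_related(
    ch: TimeSeriesChannel,
    events: EventList,
    conditions: Sequence[str],
    trial_window: tuple[float, float] = (0.0, 10.0),
    baseline_window: tuple[float, float] = (0.0, 2.0),
    measure_window: tuple[float, float] = (6.0, 7.0),
    measures: Sequence[str] = ("mean",),
    trial_measure: str = "mean",
    ci_level: float = 0.95,
    subject_name: str = "",
) -> EpochExtraction:
    """Epoch a channel around condition events.

    Each event matching a requested condition is snapped to the nearest
    sample at or after its time and yields one trial over ``trial_window``
    (half-open, seconds relative to the event).  Trials are baseline
    corrected by subtracting the mean of the non-missing samples in
    ``baseline_window``; the scalar ``trial_measure`` plus every requested
    measure are computed over ``measure_window``.  Trials whose window
    exceeds the recording are dropped and counted.  Condition average curves
    are pointwise means with a normal-theory confidence band
    (mean +- z * SE across trials).
    """
    t0, t1 = trial_window
    b0, b1 = baseline_window
    m0, m1 = measure_window
    if not t1 > t0:
        raise ValueError("trial window is empty")
    if b0 < t0 or not b1 > b0:
        raise ValueError("baseline window must be nonempty and start at or after trial start")
    if m1 > t1 or not m1 > m0:
        raise ValueError("measure window must be nonempty and end at or before trial end")
    for m in set(measures) | {trial_measure}:
        if m not in MEASURE_NAMES:
            raise ValueError(f"unknown measure name {m!r}")

    sr = ch.sample_rate
    n_trial = int(round((t1 - t0) * sr))
    bl0, bl1 = int(round((b0 - t0) * sr)), int(round((b1 - t0) * sr))
    mw0, mw1 = int(round((m0 - t0) * sr)), int(round((m1 - t0) * sr))
    rel_t0 = int(round(t0 * sr))

    matching = [ev for ev in events if ev.name in set(conditions)]
    if not matching:
        raise ValueError(f"no event matches any requested condition {tuple(conditions)}")

    per_cond: dict[str, list[tuple[float, np.ndarray]]] = {c: [] for c in conditions}
    n_dropped = 0
    for ev in matching:
        # snap to nearest sample at or after the event time
        idx = int(np.ceil((ev.time - ch.start_time) * sr - 1e-9))
        lo = idx + rel_t0
        hi = lo + n_trial
        if lo < 0 or hi > ch.n_samples:
            n_dropped += 1
            continue
        trial = ch.values[lo:hi].astype(float)
        baseline = trial[bl0:bl1]
        with np.errstate(invalid="ignore"):
            bmean = np.nanmean(baseline) if np.any(~np.isnan(baseline)) else np.nan
        per_cond[ev.name].append((ev.time, trial - bmean))

    cond_data: dict[str, ConditionEpochs] = {}
    rows: list[tuple] = []
    curve_map: dict[str, dict[str, np.ndarray]] = {}
    z = float(_sp_stats.norm.ppf(0.5 + ci_level / 2.0))
    times = t0 + np.arange(n_trial) / sr
    for cond in conditions:
        trials = per_cond[cond]
        matrix = (
            np.vstack([t for _, t in trials]) if trials else np.empty((0, n_trial))
        )
        onsets = np.asarray([onset for onset, _ in trials], dtype=float)
        trialvalues = np.asarray(
            [_measure(trial_measure, t[mw0:mw1], m0, sr) for _, t in trials], dtype=float
        )
        cond_data[cond] = ConditionEpochs(matrix, onsets, trialvalues)
        for i, (_, trial) in enumerate(trials):
            for m in measures:
                rows.append((subject_name, cond, i, m, _measure(m, trial[mw0:mw1], m0, sr)))
        if matrix.shape[0]:
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                counts = np.sum(~np.isnan(matrix), axis=0)
                mean = np.where(counts > 0, np.nanmean(matrix, axis=0), np.nan)
                sd = np.where(
                    counts > 1,
                    np.nanstd(matrix, axis=0, ddof=1),
                    np.nan,
                )
            se = sd / np.sqrt(np.maximum(counts, 1))
            curve_map[cond] = {"mean": mean, "lo": mean - z * se, "hi": mean + z * se}
        else:
            nanrow = np.full(n_trial, np.nan)
            curve_map[cond] = {"mean": nanrow, "lo": nanrow.copy(), "hi": nanrow.copy()}

    return EpochExtraction(
        data=EventRelatedData(
            conditions=cond_data,
            sample_rate=sr,
            trial_window=(t0, t1),
            measure=trial_measure,
        ),
        table=TrialMeasureTable.from_rows(rows),
        curves=ConditionCurves(times=times, curves=curve_map, level=ci_level),
        n_dropped=n_dropped,
    )


def summarize_per_subject(
    study: Study,
    conditions: Sequence[str],
    modality: str = "eyetracking",
    derived_key: str = "event_related",
) -> pd.DataFrame:
    """Conditions x subjects matrix of per-subject mean trial values
    (missing-ignoring mean; NaN where a subject has no trials)."""
    cols: dict[str, list[float]] = {}
    any_present = {c: False for c in conditions}
    for subject in study.subjects:
        erd = subject.substructures.get(modality, Modality()).derived.get(derived_key)
        col = []
        for cond in conditions:
            if erd is not None and cond in erd.conditions:
                tv = erd.conditions[cond].trialvalues
                ok = tv[~np.isnan(tv)]
                col.append(float(np.mean(ok)) if ok.size else float("nan"))
                if tv.size:
                    any_present[cond] = True
            else:
                col.append(float("nan"))
        cols[subject.name] = col
    absent = [c for c in conditions if not any_present[c]]
    if absent and study.subjects:
        raise ValueError(f"conditions absent for all subjects: {absent}")
    return pd.DataFrame(cols, index=list(conditions))


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_condition_curves(
    curves: ConditionCurves, path: str | Path, title: str = "", ylabel: str = "Pupil size"
) -> Path:
    """Write the per-condition average curves with confidence bands to an
    image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, c in curves.curves.items():
        (line,) = ax.plot(curves.times, c["mean"], label=cond)
        ax.fill_between(curves.times, c["lo"], c["hi"], alpha=0.25, color=line.get_color())
    ax.set_xlabel("Time from trial onset (s)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# plugin wrappers
# ---------------------------------------------------------------------------


def _channel_selection(mod: Modality, setting: Any) -> list[str]:
    if setting in (None, "all", "*"):
        return list(mod.channels)
    return [c for c in setting if c in mod.channels]


def _declare_read_file() -> PluginSpec:
    return PluginSpec(
        plugin_id="core/read_file",
        category="core",
        doc="Flexible columnar text-file reader (channels + events).",
        settings_schema={
            "modality": SettingSpec("str", default="eyetracking"),
            "file_pattern": SettingSpec("str", default="*", doc="raw file name pattern"),
            "timestamp_column": SettingSpec("str", default="Timestamp"),
            "timestamp_unit": SettingSpec("str", default="ms", choices=("ms", "s")),
            "channel_columns": SettingSpec(
                "dict", default={}, doc="file column -> channel name"
            ),
            "event_column": SettingSpec("str", default="", doc="empty = no events"),
            "missing_codes": SettingSpec("dict", default={}),
            "sample_rate": SettingSpec("float", default=None, nullable=True, minimum=0.0),
            "separator": SettingSpec("str", default="\t"),
        },
    )


def _process_read_file(study: Study, subject: Subject, settings: dict, ctx) -> None:
    names = sorted(
        n for n in subject.raw_files if fnmatch.fnmatchcase(n, settings["file_pattern"])
    )
    if not names:
        raise FileNotFoundError(
            f"subject {subject.name!r}: no raw file matches {settings['file_pattern']!r}"
        )
    cmap = ColumnMap(
        timestamp_column=settings["timestamp_column"],
        channels=dict(settings["channel_columns"]),
        event_column=settings["event_column"] or None,
        timestamp_unit=settings["timestamp_unit"],
        missing_codes={k: list(v) for k, v in settings["missing_codes"].items()},
        sample_rate=settings["sample_rate"],
        separator=settings["separator"],
    )
    subject.substructures[settings["modality"]] = read_columnar_file(
        subject.raw_files[names[0]].decode("utf-8"), cmap
    )


def _declare_modify_events() -> PluginSpec:
    return PluginSpec(
        plugin_id="core/modify_events",
        category="core",
        doc="Rename events by ordered (pattern -> new name) rules.",
        settings_schema={
            "modality": SettingSpec("str", default="eyetracking"),
            "rules": SettingSpec("list", default=[], doc="list of [pattern, new_name]"),
        },
    )


def _process_modify_events(study: Study, subject: Subject, settings: dict, ctx) -> None:
    mod = subject.substructures[settings["modality"]]
    mod.events = modify_events(mod.events, [tuple(r) for r in settings["rules"]])


def _declare_interpolate() -> PluginSpec:
    return PluginSpec(
        plugin_id="core/interpolate_gaps",
        category="core",
        doc="Fill short missing-data runs by nearest/linear/cubic interpolation.",
        settings_schema={
            "modality": SettingSpec("str", default="eyetracking"),
            "channels": SettingSpec("list", default=None, nullable=True),
            "max_gap": SettingSpec("int", default=5, minimum=1),
            "method": SettingSpec(
                "str", default="linear", choices=("nearest", "linear", "cubic")
            ),
            "max_jump": SettingSpec("float", default=None, nullable=True, minimum=0.0),
            "valid_range": SettingSpec("pair", default=None, nullable=True),
        },
    )


def _process_interpolate(study: Study, subject: Subject, settings: dict, ctx) -> None:
    mod = subject.substructures[settings["modality"]]
    vr = settings["valid_range"]
    for name in _channel_selection(mod, settings["channels"]):
        mod.channels[name] = interpolate_gaps(
            mod.channels[name],
            max_gap=settings["max_gap"],
            method=settings["method"],
            max_jump=settings["max_jump"],
            valid_range=tuple(vr) if vr is not None else None,
        )


def _declare_filter() -> PluginSpec:
    return PluginSpec(
        plugin_id="core/filter_moving_average",
        category="core",
        doc=(
            "Zero-phase sliding-window mean/median filter; optionally followed "
            "by a mean-smoothing pass with the same half-width."
        ),
        settings_schema={
            "modality": SettingSpec("str", default="eyetracking"),
            "channels": SettingSpec("list", default=None, nullable=True),
            "halfwidth": SettingSpec("int", default=5, minimum=0),
            "statistic": SettingSpec("str", default="mean", choices=("mean", "median")),
            "then_mean": SettingSpec(
                "bool",
                default=False,
                doc="apply a second, mean-statistic pass with the same half-width",
            ),
        },
    )


def _process_filter(study: Study, subject: Subject, settings: dict, ctx) -> None:
    mod = subject.substructures[settings["modality"]]
    for name in _channel_selection(mod, settings["channels"]):
        ch = moving_filter(mod.channels[name], settings["halfwidth"], settings["statistic"])
        if settings["then_mean"]:
            ch = moving_filter(ch, settings["halfwidth"], "mean")
        mod.channels[name] = ch


def _declare_extract() -> PluginSpec:
    return PluginSpec(
        plugin_id="core/event_related_extraction",
        category="core",
        scope="group",
        doc="Epoch a channel around condition events; baseline correction, "
        "per-trial measures, condition average curves.",
        settings_schema={
            "modality": SettingSpec("str", default="eyetracking"),
            "channel": SettingSpec("str", default="pupil"),
            "conditions": SettingSpec("list", default=["easy", "medium", "difficult"]),
            "trial_window": SettingSpec("pair", default=[0.0, 10.0]),
            "baseline_window": SettingSpec("pair", default=[0.0, 2.0]),
            "measure_window": SettingSpec("pair", default=[6.0, 7.0]),
            "measures": SettingSpec("list", default=["mean"]),
            "trial_measure": SettingSpec("str", default="mean", choices=MEASURE_NAMES),
            "ci_level": SettingSpec("float", default=0.95, minimum=0.0, maximum=1.0),
        },
    )


def _process_extract(
    study: Study, subjects: list[Subject], settings: dict, ctx
) -> dict[str, Any]:
    combined: TrialMeasureTable | None = None
    dropped = 0
    for subject in subjects:
        mod = subject.substructures[settings["modality"]]
        result = extract_event_related(
            mod.channels[settings["channel"]],
            mod.events,
            conditions=list(settings["conditions"]),
            trial_window=tuple(settings["trial_window"]),
            baseline_window=tuple(settings["baseline_window"]),
            measure_window=tuple(settings["measure_window"]),
            measures=list(settings["measures"]),
            trial_measure=settings["trial_measure"],
            ci_level=settings["ci_level"],
            subject_name=subject.name,
        )
        mod.derived["event_related"] = result.data
        mod.derived["trial_measures"] = result.table
        mod.derived["condition_curves"] = result.curves
        combined = result.table if combined is None else combined.concat(result.table)
        dropped += result.n_dropped
        if ctx is not None:
            ctx.tick()
    outputs: dict[str, Any] = {"trial_measures": combined, "n_dropped_trials": dropped}
    if ctx is not None and ctx.output_dir is not None and combined is not None:
        table_path = Path(ctx.output_dir) / "trial_measures.tsv"
        combined.to_tsv(table_path)
        outputs["table_path"] = str(table_path)
        # grand-average curves pooled over subjects' trials
        pooled = _pooled_curves(subjects, settings)
        if pooled is not None:
            plot_path = plot_condition_curves(
                pooled,
                Path(ctx.output_dir) / "condition_averages.png",
                title="Average pupil size per condition",
            )
            outputs["plot_path"] = str(plot_path)
    return outputs


def _pooled_curves(subjects: list[Subject], settings: dict) -> ConditionCurves | None:
    mats: dict[str, list[np.ndarray]] = {c: [] for c in settings["conditions"]}
    sr = None
    t0 = float(settings["trial_window"][0])
    for subject in subjects:
        erd = subject.substructures[settings["modality"]].derived.get("event_related")
        if erd is None:
            continue
        sr = erd.sample_rate
        for cond in settings["conditions"]:
            if cond in erd.conditions and erd.conditions[cond].matrix.size:
                mats[cond].append(erd.conditions[cond].matrix)
    if sr is None:
        return None
    z = float(_sp_stats.norm.ppf(0.5 + settings["ci_level"] / 2.0))
    curves = {}
    n_samp = None
    for cond, blocks in mats.items():
        if not blocks:
            continue
        m = np.vstack(blocks)
        n_samp = m.shape[1]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            counts = np.sum(~np.isnan(m), axis=0)
            mean = np.where(counts > 0, np.nanmean(m, axis=0), np.nan)
            sd = np.where(counts > 1, np.nanstd(m, axis=0, ddof=1), np.nan)
        se = sd / np.sqrt(np.maximum(counts, 1))
        curves[cond] = {"mean": mean, "lo": mean - z * se, "hi": mean + z * se}
    if n_samp is None:
        return None
    times = t0 + np.arange(n_samp) / sr
    return ConditionCurves(times=times, curves=curves, level=settings["ci_level"])


def _identity_configure(settings: dict) -> dict:
    return dict(settings)


def register_core_plugins(registry=None) -> None:
    registry = registry or default_registry
    for declare, process in (
        (_declare_read_file, _process_read_file),
        (_declare_modify_events, _process_modify_events),
        (_declare_interpolate, _process_interpolate),
        (_declare_filter, _process_filter),
        (_declare_extract, _process_extract),
    ):
        if declare().plugin_id not in registry:
            registry.register(declare, _identity_configure, process)


register_core_plugins()
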