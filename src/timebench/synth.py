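"""Synthetic eyetracker recordings of a mental-multiplication experiment.

Each trial shows a blank screen for 2 s, the multiplicand at 2 s and the
multiplier at 4 s; the subject multiplies the numbers silently.  Operand
pairs come from three difficulty conditions (easy 1-9, medium 6-14,
difficult 11-19).  The task-evoked pupillary response is modelled as a
smooth log-normal-shaped bump added to a constant baseline, peaking 6.5 s
after trial onset (within the 6-8 s window where cognitive load shows), with
amplitude scaled by condition difficulty and a per-subject multiplicative
gain.  Realistic nuisance structure is added: Gaussian sensor noise, blink
gaps (runs of missing samples in pupil and gaze), isolated spurious pupil
outliers, and slowly wandering gaze around screen centre.

Recordings are written in a ClearView-like "combined" tab-separated dialect
(gaze x/y, pupil and event labels in one file per subject; integer
millisecond timestamps; missing code ``-1``), which the columnar file reader
parses back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Event, Modality, Study, Subject, TimeSeriesChannel
from .plugins_core import ColumnMap

__all__ = [
    "SimulationConfig",
    "CONDITION_RANGES",
    "pupil_response_kernel",
    "generate_stimulus_set",
    "simulate_recording",
    "simulate_study",
    "write_clearview_file",
    "clearview_text",
    "clearview_column_map",
]

#: Operand ranges (inclusive) per difficulty condition.
CONDITION_RANGES: dict[str, tuple[int, int]] = {
    "easy": (1, 9),
    "medium": (6, 14),
    "difficult": (11, 19),
}

CONDITIONS = tuple(CONDITION_RANGES)


@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    Amplitudes are millimetres of peak pupil dilation per condition
    (easy, medium, difficult).  Blink gaps are placed at ``blink_rate_per_min``
    with lengths (in samples) drawn from ``blink_length_probs``; spurious
    outliers are isolated single-sample pupil excursions of
    ``outlier_magnitude`` mm.
    """

    n_subjects: int = 10
    trials_per_condition: int = 12
    sample_rate: float = 50.0  # Hz
    baseline_pupil: float = 3.5  # mm
    noise_sd: float = 0.05  # mm
    blink_rate_per_min: float = 4.0
    blink_length_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.35, 3: 0.30, 4: 0.20, 6: 0.10, 8: 0.05}
    )
    outlier_rate_per_min: float = 6.0
    outlier_magnitude: float = 1.0  # mm
    amplitudes: tuple[float, float, float] = (0.05, 0.15, 0.30)  # mm
    kernel_peak: float = 6.5  # s after trial onset
    kernel_width: float = 0.25  # log-domain sd of the response bump
    trial_duration: float = 10.0  # s
    inter_trial_interval: float = 5.0  # s; long enough for baseline recovery
    subject_gain_sd: float = 0.15  # log-normal sd of per-subject response gain
    screen: tuple[int, int] = (1280, 1024)
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        for rate in (self.blink_rate_per_min, self.outlier_rate_per_min):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one subject and one trial per condition")
        if abs(sum(self.blink_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("blink_length_probs must sum to 1")


def pupil_response_kernel(
    t: np.ndarray, peak: float = 6.5, width: float = 0.25
) -> np.ndarray:
    """Unimodal log-normal-shaped response bump, unit height at ``t = peak``,
    zero for ``t <= 0``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(-((np.log(t[pos] / peak)) ** 2) / (2.0 * width**2))
    return out


def generate_stimulus_set(
    rng: np.random.Generator, trials_per_condition: int
) -> list[tuple[str, int, int]]:
    """Draw a study-wide stimulus list: per condition, operand pairs sampled
    uniformly from the condition's range, globally unique across conditions
    (the ranges overlap) so each raw trigger name maps to one condition."""
    used: set[tuple[int, int]] = set()
    stimuli: list[tuple[str, int, int]] = []
    for cond in CONDITIONS:
        lo, hi = CONDITION_RANGES[cond]
        n_possible = (hi - lo + 1) ** 2
        if trials_per_condition > n_possible - len(used):
            raise ValueError(f"not enough distinct operand pairs for {cond!r}")
        drawn = 0
        while drawn < trials_per_condition:
            pair = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
            if pair in used:
                continue
            used.add(pair)
            stimuli.append((cond, *pair))
            drawn += 1
    return stimuli


def trigger_name(a: int, b: int) -> str:
    """Raw stimulus-onset trigger label as exported by the tracker."""
    return f"stim_{a}x{b}"


def simulate_recording(
    cfg: SimulationConfig,
    subject_name: str,
    stimuli: Sequence[tuple[str, int, int]] | None = None,
    seed: int | None = None,
):
    """Simulate one subject's recording.

    Returns ``(modality, schedule)`` where ``schedule`` is the ground-truth
    trial list: dicts with trial index, condition, operands and onset time.
    Stimulus order is shuffled per subject; events are emitted at onset
    (raw trigger name), onset + 2 s (multiplicand) and onset + 4 s
    (multiplier).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if stimuli is None:
        stimuli = generate_stimulus_set(rng, cfg.trials_per_condition)
    order = rng.permutation(len(stimuli))
    sr = cfg.sample_rate
    dt = 1.0 / sr
    spacing = cfg.trial_duration + cfg.inter_trial_interval
    onsets = 2.0 + np.arange(len(stimuli)) * spacing
    duration = onsets[-1] + spacing
    n = int(round(duration * sr))
    t = np.arange(n) * dt

    gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd)))
    amp = dict(zip(CONDITIONS, cfg.amplitudes))

    pupil = np.full(n, cfg.baseline_pupil, dtype=float)
    schedule = []
    mod = Modality()
    for trial_i, stim_i in enumerate(order):
        cond, a, b = stimuli[stim_i]
        onset = float(onsets[trial_i])
        pupil += gain * amp[cond] * pupil_response_kernel(
            t - onset, cfg.kernel_peak, cfg.kernel_width
        )
        schedule.append(
            {"trial": trial_i, "condition": cond, "a": a, "b": b, "onset": onset}
        )
        mod.events.add(Event(trigger_name(a, b), onset))
        mod.events.add(Event("multiplicand", onset + 2.0))
        mod.events.add(Event("multiplier", onset + 4.0))

    if cfg.noise_sd > 0:
        pupil += rng.normal(0.0, cfg.noise_sd, size=n)

    # gaze: AR(1) wander around screen centre
    from scipy.signal import lfilter

    cx, cy = cfg.screen[0] / 2.0, cfg.screen[1] / 2.0
    eps = rng.normal(0.0, 3.0, size=(2, n))
    eps[:, 0] = 0.0
    gaze = np.asarray([[cx], [cy]]) + lfilter([1.0], [1.0, -0.98], eps, axis=1)

    # isolated spurious pupil outliers
    minutes = duration / 60.0
    n_out = rng.poisson(cfg.outlier_rate_per_min * minutes)
    if n_out and cfg.outlier_magnitude > 0:
        idx = rng.integers(0, n, size=n_out)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        pupil[idx] += signs * cfg.outlier_magnitude

    # blink gaps: non-overlapping, non-adjacent missing runs in pupil and gaze
    n_blinks = rng.poisson(cfg.blink_rate_per_min * minutes)
    lengths = np.array(sorted(cfg.blink_length_probs), dtype=int)
    probs = np.array([cfg.blink_length_probs[int(k)] for k in lengths])
    occupied = np.zeros(n, dtype=bool)
    for _ in range(n_blinks):
        length = int(rng.choice(lengths, p=probs))
        for _attempt in range(50):
            start = int(rng.integers(1, max(2, n - length - 1)))
            lo, hi = max(0, start - 1), min(n, start + length + 1)
            if not occupied[lo:hi].any():
                occupied[start : start + length] = True
                pupil[start : start + length] = np.nan
                gaze[:, start : start + length] = np.nan
                break

    mod.channels["gaze_x"] = TimeSeriesChannel("gaze_x", sr, gaze[0], units="px")
    mod.channels["gaze_y"] = TimeSeriesChannel("gaze_y", sr, gaze[1], units="px")
    mod.channels["pupil"] = TimeSeriesChannel("pupil", sr, pupil, units="mm")
    return mod, schedule


# ---------------------------------------------------------------------------
# ClearView-like combined dialect
# ---------------------------------------------------------------------------

_HEADER = "Timestamp\tGazeX\tGazeY\tPupil\tEvent"
_MISSING_CODE = "-1"


def clearview_text(mod: Modality) -> str:
    """Render a modality in the combined dialect: tab-separated, header row,
    integer millisecond timestamps, missing code -1, event labels only on
    event rows (gaze and events share the one file)."""
    for required in ("gaze_x", "gaze_y", "pupil"):
        if required not in mod.channels:
            raise ValueError(f"modality lacks required channel {required!r}")
    pupil = mod.channels["pupil"]
    sr, start = pupil.sample_rate, pupil.start_time
    n = pupil.n_samples
    event_cells = [""] * n
    for ev in mod.events:
        idx = int(np.ceil((ev.time - start) * sr - 1e-9))
        if 0 <= idx < n:
            event_cells[idx] = ev.name

    def fmt(v: float) -> str:
        return _MISSING_CODE if np.isnan(v) else repr(float(v))

    gx, gy, pv = (mod.channels[c].values for c in ("gaze_x", "gaze_y", "pupil"))
    lines = [_HEADER]
    for i in range(n):
        ts = int(round((start + i / sr) * 1000.0))
        lines.append(f"{ts}\t{fmt(gx[i])}\t{fmt(gy[i])}\t{fmt(pv[i])}\t{event_cells[i]}")
    return "\n".join(lines) + "\n"


def write_clearview_file(mod: Modality, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(clearview_text(mod))
    return path


def clearview_column_map(sample_rate: float | None = 50.0) -> ColumnMap:
    """Column map under which the reader parses the combined dialect."""
    return ColumnMap(
        timestamp_column="Timestamp",
        channels={"GazeX": "gaze_x", "GazeY": "gaze_y", "Pupil": "pupil"},
        event_column="Event",
        timestamp_unit="ms",
        missing_codes={c: [_MISSING_CODE] for c in ("GazeX", "GazeY", "Pupil")},
        sample_rate=sample_rate,
    )


def write_schedule_file(schedule: list[dict], path: str | Path) -> Path:
    """Ground-truth trial schedule as a TSV alongside the recording."""
    path = Path(path)
    lines = ["trial\tcondition\ta\tb\tonset"]
    for row in schedule:
        lines.append(
            f"{row['trial']}\t{row['condition']}\t{row['a']}\t{row['b']}\t{row['onset']!r}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_study(cfg: SimulationConfig, name: str = "synthetic-study"):
    """Build a full synthetic study: one shared stimulus set, one combined
    raw file per subject (attached byte-exact), plus the ground-truth
    schedules.

    Returns ``(study, stimuli, schedules)``; the study carries only raw
    files, ready for a workflow whose first stage is the file reader.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    stimuli = generate_stimulus_set(rng, cfg.trials_per_condition)
    study = Study(name=name)
    schedules: dict[str, list[dict]] = {}
    for s in range(cfg.n_subjects):
        subject_name = f"subject{s + 1:02d}"
        sub_seed = int(rng.integers(0, 2**31))
        mod, schedule = simulate_recording(cfg, subject_name, stimuli, seed=sub_seed)
        subject = Subject(name=subject_name)
        subject.raw_files[f"{subject_name}_combined.tsv"] = clearview_text(mod).encode()
        study.add_subject(subject)
        schedules[subject_name] = schedule
    return study, stimuli, schedules
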