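"""Workflow execution: apply selected plugins to selected subjects in
workflow order, with progress, structured logging and provenance.

Determinism contract: given an identical study, selections, settings and
seed, a run produces bit-identical derived data and report (timestamps
excluded).  Every stochastic plugin receives a random stream derived from
``hash(seed, plugin_id, subject_name)``, so reproducibility does not depend
on selection order.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable

import numpy as np

from . import __version__
from .model import (
    ProvenanceRecord,
    Study,
    content_hash,
    modality_state,
)
from .plugin_api import PluginRegistry, default_registry

logger = logging.getLogger("timebench.engine")

__all__ = ["run_workflow", "RunReport", "StageResult", "derive_seed", "WorkflowError"]


class WorkflowError(RuntimeError):
    """A plugin failed and the error policy is 'abort'."""


def derive_seed(seed: int, plugin_id: str, subject_name: str) -> int:
    """Per-(plugin, subject) substream seed, below 2**31."""
    digest = hashlib.sha256(f"{seed}|{plugin_id}|{subject_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StageResult:
    plugin_id: str
    settings_name: str
    subject: str | None  # None for group-scope stages
    status: str  # "ok" | "failed" | "skipped"
    duration: float = 0.0
    message: str = ""
    outputs: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunReport:
    seed: int
    stages: list[StageResult] = field(default_factory=list)
    completed_units: int = 0
    total_units: int = 0

    @property
    def completed_fraction(self) -> float:
        return self.completed_units / self.total_units if self.total_units else 1.0

    @property
    def ok(self) -> bool:
        return all(s.status == "ok" for s in self.stages)

    @property
    def failures(self) -> list[tuple[str, str | None]]:
        return [(s.plugin_id, s.subject) for s in self.stages if s.status == "failed"]

    def outputs_for(self, plugin_id: str) -> dict[str, Any]:
        merged: dict[str, Any] = {}
        for s in self.stages:
            if s.plugin_id == plugin_id:
                merged.update(s.outputs)
        return merged

    def to_table(self) -> str:
        lines = ["plugin\tsettings\tsubject\tstatus\tduration_s\tmessage"]
        for s in self.stages:
            lines.append(
                f"{s.plugin_id}\t{s.settings_name}\t{s.subject or '-'}\t{s.status}"
                f"\t{s.duration:.3f}\t{s.message}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class ExecutionContext:
    """Per-stage context handed to plugin ``process`` entry points."""

    seed: int
    plugin_id: str
    output_dir: Path | None
    registry: PluginRegistry
    _progress: Callable[[], None] | None = None

    def seed_for(self, subject_name: str) -> int:
        return derive_seed(self.seed, self.plugin_id, subject_name)

    def rng_for(self, subject_name: str) -> np.random.Generator:
        return np.random.default_rng(self.seed_for(subject_name))

    def tick(self) -> None:
        """Group plugins call this once per subject to advance progress."""
        if self._progress is not None:
            self._progress()


def run_workflow(
    study: Study,
    subject_selection: list[int] | None = None,
    plugin_selection: list[int] | None = None,
    seed: int = 0,
    registry: PluginRegistry | None = None,
    on_error: str = "abort",
    output_dir: str | Path | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> RunReport:
    """Execute the selected workflow stages over the selected subjects.

    Selections are index sets into ``study.subjects`` / ``study.workflow``
    (``None`` selects all).  Stages are applied in workflow order, each to
    every selected subject; unselected subjects are untouched.  One
    provenance record is appended per executed stage.  ``on_error`` is
    ``"abort"`` (stop at the first failure) or ``"continue"`` (record the
    failing (plugin, subject) pair and keep going).
    """
    registry = registry or default_registry
    study.check_unlocked()
    if on_error not in ("abort", "continue"):
        raise ValueError(f"unknown error policy {on_error!r}")
    n_subj, n_stages = len(study.subjects), len(study.workflow)
    subject_idx = sorted(set(range(n_subj) if subject_selection is None else subject_selection))
    plugin_idx = sorted(set(range(n_stages) if plugin_selection is None else plugin_selection))
    if any(i < 0 or i >= n_subj for i in subject_idx):
        raise IndexError("subject selection out of range")
    if any(i < 0 or i >= n_stages for i in plugin_idx):
        raise IndexError("plugin selection out of range")

    subjects = [study.subjects[i] for i in subject_idx]
    subject_names = [s.name for s in subjects]
    report = RunReport(seed=seed, total_units=len(plugin_idx) * len(subjects))
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)

    def advance() -> None:
        report.completed_units += 1
        if progress is not None:
            progress(report.completed_units, report.total_units)

    aborted = False
    for stage_i in plugin_idx:
        if aborted:
            break
        instance = study.workflow[stage_i]
        entry = registry.get(instance.plugin_id)
        settings = entry.spec.validate(instance.settings)
        settings = entry.configure(settings)
        settings_hash = content_hash(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in settings.items()}
        )
        input_hash = content_hash(modality_state(study, subject_names))
        ctx = ExecutionContext(
            seed=seed,
            plugin_id=instance.plugin_id,
            output_dir=output_dir,
            registry=registry,
            _progress=advance,
        )
        if entry.spec.scope == "group":
            units_before = report.completed_units
            t0 = time.perf_counter()
            try:
                outputs = entry.process(study, subjects, settings, ctx) or {}
                status, message = "ok", ""
            except Exception as exc:  # noqa: BLE001 - reported per stage
                outputs, status, message = {}, "failed", f"{type(exc).__name__}: {exc}"
            duration = time.perf_counter() - t0
            report.stages.append(
                StageResult(
                    instance.plugin_id, instance.settings_name, None, status,
                    duration, message, outputs,
                )
            )
            logger.info(
                "stage=%s subjects=%d status=%s duration=%.3fs",
                instance.plugin_id, len(subjects), status, duration,
            )
            if status == "failed":
                logger.error("stage=%s failed: %s", instance.plugin_id, message)
                if on_error == "abort":
                    aborted = True
            else:
                # group stages may advance per subject via ctx.tick(); top up
                # whatever remains so progress reflects plugins x subjects
                for _ in range(units_before + len(subjects) - report.completed_units):
                    advance()
        else:
            for subject in subjects:
                t0 = time.perf_counter()
                try:
                    outputs = entry.process(study, subject, settings, ctx) or {}
                    status, message = "ok", ""
                except Exception as exc:  # noqa: BLE001
                    outputs, status, message = {}, "failed", f"{type(exc).__name__}: {exc}"
                duration = time.perf_counter() - t0
                report.stages.append(
                    StageResult(
                        instance.plugin_id, instance.settings_name, subject.name,
                        status, duration, message, outputs,
                    )
                )
                logger.info(
                    "stage=%s subject=%s status=%s duration=%.3fs",
                    instance.plugin_id, subject.name, status, duration,
                )
                advance()
                if status == "failed":
                    logger.error(
                        "stage=%s subject=%s failed: %s",
                        instance.plugin_id, subject.name, message,
                    )
                    if on_error == "abort":
                        aborted = True
                        break

        output_hash = content_hash(modality_state(study, subject_names))
        study.provenance.append(
            ProvenanceRecord(
                timestamp=datetime.now(timezone.utc).isoformat(),
                plugin_id=instance.plugin_id,
                settings_hash=settings_hash,
                subjects=list(subject_names),
                engine_version=__version__,
                input_hash=input_hash,
                output_hash=output_hash,
            )
        )
        # snapshot the plugin source into the study so any run leaves the
        # workflow self-contained
        if instance.source_ref is None:
            instance.source_ref = instance.plugin_id
        study.plugin_sources.setdefault(
            instance.source_ref, registry.source_for(instance.plugin_id)
        )

    if output_dir is not None:
        (output_dir / "run_report.tsv").write_text(report.to_table())
    return report
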