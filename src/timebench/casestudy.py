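"""The shipped pupillometry case-study workflow and its bootstrap extension.

The five-stage workflow reconstructs a standard event-related pupillometry
analysis of the mental-multiplication experiment:

1. read the combined gaze/pupil/event export (one file per subject);
2. recode raw stimulus-onset triggers into the conditions easy / medium /
   difficult;
3. linearly interpolate missing-data gaps strictly shorter than 5 samples;
4. moving median filter with half-width 5 (an 11-sample zero-phase window)
   to remove spurious outlier pupil sizes, followed by a moving mean with
   the same window to smooth;
5. extract trials at the condition events, baseline-correct over [0, 2) s,
   and take the mean pupil size over [6, 7) s as the per-trial measure.

The ``test/bootstrap`` group plugin then compares per-subject condition
means between the easiest and hardest condition with a 5000-resample
two-sample bootstrap and plots the per-subject means as a line plot titled
with the p-value.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

from .model import PluginInstance, Study, Subject
from .plugin_api import PluginSpec, SettingSpec, default_registry, instantiate
from .plugins_core import summarize_per_subject
from .stats import bootstrap_pvalue
from .synth import (
    CONDITIONS,
    SimulationConfig,
    clearview_column_map,
    simulate_study,
    trigger_name,
)

__all__ = [
    "build_workflow",
    "build_case_study",
    "bootstrap_stage",
    "rename_rules",
    "CASE_STUDY_PARAMS",
]

#: The case-study stage parameters (gap threshold is strict: gaps of length
#: 5 are left untouched, 4 and below are filled).
CASE_STUDY_PARAMS = {
    "max_gap": 5,
    "interpolation": "linear",
    "filter_halfwidth": 5,
    "filter_statistic": "median",
    "smooth_after_median": True,
    "baseline_window": [0.0, 2.0],
    "measure_window": [6.0, 7.0],
    "trial_window": [0.0, 10.0],
    "bootstrap_resamples": 5000,
}


def rename_rules(stimuli: Sequence[tuple[str, int, int]]) -> list[list[str]]:
    """Literal (trigger -> condition) rules derived from the stimulus list."""
    return [[trigger_name(a, b), cond] for cond, a, b in stimuli]


def build_workflow(
    stimuli: Sequence[tuple[str, int, int]],
    sample_rate: float = 50.0,
    registry=None,
) -> list[PluginInstance]:
    """The five-stage case-study workflow, in order."""
    registry = registry or default_registry
    cmap = clearview_column_map(sample_rate)
    p = CASE_STUDY_PARAMS
    return [
        instantiate(
            "core/read_file",
            overrides={
                "modality": "eyetracking",
                "file_pattern": "*_combined.tsv",
                "timestamp_column": cmap.timestamp_column,
                "timestamp_unit": cmap.timestamp_unit,
                "channel_columns": dict(cmap.channels),
                "event_column": cmap.event_column,
                "missing_codes": {k: list(v) for k, v in cmap.missing_codes.items()},
                "sample_rate": sample_rate,
            },
            registry=registry,
        ),
        instantiate(
            "core/modify_events",
            overrides={"rules": rename_rules(stimuli)},
            registry=registry,
        ),
        instantiate(
            "core/interpolate_gaps",
            overrides={"max_gap": p["max_gap"], "method": p["interpolation"]},
            registry=registry,
        ),
        instantiate(
            "core/filter_moving_average",
            overrides={
                "channels": ["pupil"],
                "halfwidth": p["filter_halfwidth"],
                "statistic": p["filter_statistic"],
                "then_mean": p["smooth_after_median"],
            },
            registry=registry,
        ),
        instantiate(
            "core/event_related_extraction",
            overrides={
                "channel": "pupil",
                "conditions": list(CONDITIONS),
                "trial_window": p["trial_window"],
                "baseline_window": p["baseline_window"],
                "measure_window": p["measure_window"],
                "measures": ["mean"],
                "trial_measure": "mean",
            },
            registry=registry,
        ),
    ]


def build_case_study(
    cfg: SimulationConfig | None = None,
    name: str = "mental-multiplication",
    with_bootstrap: bool = False,
    registry=None,
) -> Study:
    """Synthetic study with raw files attached and the workflow installed."""
    cfg = cfg or SimulationConfig()
    study, stimuli, _ = simulate_study(cfg, name=name)
    for stage in build_workflow(stimuli, cfg.sample_rate, registry=registry):
        study.append_stage(stage)
    if with_bootstrap:
        study.append_stage(bootstrap_stage(registry=registry))
    return study


# ---------------------------------------------------------------------------
# the custom bootstrap plugin (group scope)
# ---------------------------------------------------------------------------


def _declare_bootstrap() -> PluginSpec:
    return PluginSpec(
        plugin_id="test/bootstrap",
        category="custom/test",
        scope="group",
        doc="Per-subject condition means, group line plot, and a two-sample "
        "bootstrap p-value between the first and last condition.",
        settings_schema={
            "modality": SettingSpec("str", default="eyetracking"),
            "conditions": SettingSpec("list", default=list(CONDITIONS)),
            "group_a": SettingSpec("str", default="easy"),
            "group_b": SettingSpec("str", default="difficult"),
            "n_resamples": SettingSpec("int", default=5000, minimum=1),
        },
    )


def _process_bootstrap(
    study: Study, subjects: list[Subject], settings: dict, ctx
) -> dict[str, Any]:
    if not subjects:
        return {}
    means = summarize_per_subject(
        study, settings["conditions"], modality=settings["modality"]
    )
    means = means[[s.name for s in subjects if s.name in means.columns]]
    result = bootstrap_pvalue(
        means.loc[settings["group_a"]].to_numpy(),
        means.loc[settings["group_b"]].to_numpy(),
        n_resamples=settings["n_resamples"],
        seed=ctx.seed_for("group") if ctx is not None else 0,
    )
    outputs: dict[str, Any] = {
        "p_value": result.p_value,
        "statistic": result.statistic,
        "condition_means": means,
        "bootstrap": result,
    }
    if ctx is not None and ctx.output_dir is not None:
        outputs["plot_path"] = str(
            _plot_subject_means(
                means,
                Path(ctx.output_dir) / "subject_condition_means.png",
                title=(
                    f"Bootstrapped p-value between {settings['group_a']} and "
                    f"{settings['group_b']}: {result.p_value:.3f}"
                ),
            )
        )
    return outputs


def _plot_subject_means(means, path: Path, title: str) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    x = range(1, len(means.index) + 1)
    for subject in means.columns:
        ax.plot(x, means[subject].to_numpy(), ".-", markersize=10)
    ax.set_xlim(0, len(means.index) + 1)
    ax.set_xticks(list(x))
    ax.set_xticklabels(list(means.index))
    ax.set_ylabel("Pupil size")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _configure_bootstrap(settings: dict) -> dict:
    return dict(settings)


def bootstrap_stage(registry=None) -> PluginInstance:
    """The bootstrap extension stage, saved under the settings name 'noName'."""
    inst = instantiate("test/bootstrap", registry=registry or default_registry)
    inst.settings_name = "noName"
    return inst


def register_case_study_plugins(registry=None) -> None:
    registry = registry or default_registry
    if "test/bootstrap" not in registry:
        registry.register(_declare_bootstrap, _configure_bootstrap, _process_bootstrap)


register_case_study_plugins()
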