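"""Workflow execution semantics: ordering, determinism, error policy,
provenance and progress."""

import copy

import numpy as np
import pytest

from timebench import (
    LockedStudyError,
    Study,
    Subject,
    derived_hash,
    instantiate,
    interpolate_gaps,
    moving_filter,
)
from timebench.engine import derive_seed, run_workflow
from timebench.model import modality_state
from timebench.plugin_api import PluginRegistry, PluginSpec, SettingSpec

from conftest import make_channel
from timebench.model import Modality


def _gap_study():
    """Channel where interpolation and median filtering do not commute."""
    values = np.array([0.0, 0.0, np.nan, np.nan, np.nan, np.nan, 10.0, 10.0, 0.0, 0.0])
    mod = Modality(channels={"pupil": make_channel(values)})
    study = Study(name="gap")
    study.add_subject(Subject(name="s1", substructures={"eyetracking": mod}))
    return study


def _stage(plugin_id, **overrides):
    return instantiate(plugin_id, overrides=overrides)


class TestRunWorkflow:
    def test_empty_plugin_selection_is_a_noop(self, toy_study):
        before = modality_state(toy_study, ["s1"])
        report = run_workflow(toy_study, plugin_selection=[])
        assert report.stages == []
        assert report.completed_fraction == 1.0
        assert modality_state(toy_study, ["s1"]) == before

    def test_engine_composition_matches_manual_calls(self, toy_study):
        manual = copy.deepcopy(toy_study)
        ch = manual.subject("s1").substructures["eyetracking"].channels["pupil"]
        expected = moving_filter(interpolate_gaps(ch, max_gap=5, method="linear"), 2, "median")

        toy_study.append_stage(_stage("core/interpolate_gaps", max_gap=5, method="linear"))
        toy_study.append_stage(
            _stage("core/filter_moving_average", halfwidth=2, statistic="median")
        )
        report = run_workflow(toy_study)
        assert report.ok
        got = toy_study.subject("s1").substructures["eyetracking"].channels["pupil"]
        assert got == expected

    def test_stage_order_is_honoured(self):
        """Median filtering fills gap samples from their neighbourhood, so
        swapping it with gap interpolation changes the result."""
        a, b = _gap_study(), _gap_study()
        interp = _stage("core/interpolate_gaps", max_gap=10, method="linear")
        filt = _stage("core/filter_moving_average", halfwidth=1, statistic="median")
        a.workflow = [interp, filt]
        b.workflow = [copy.deepcopy(filt), copy.deepcopy(interp)]
        assert run_workflow(a).ok and run_workflow(b).ok
        ch_a = a.subject("s1").substructures["eyetracking"].channels["pupil"]
        ch_b = b.subject("s1").substructures["eyetracking"].channels["pupil"]
        assert ch_a != ch_b

    def test_unselected_subjects_untouched(self, small_cfg):
        from timebench.casestudy import build_case_study

        study = build_case_study(small_cfg)
        report = run_workflow(study, subject_selection=[0])
        assert report.ok
        assert study.subjects[0].substructures  # processed
        assert not study.subjects[1].substructures  # untouched

    def test_determinism_same_seed_same_hash_and_report(self, small_cfg):
        from timebench.casestudy import build_case_study

        runs = []
        for _ in range(2):
            study = build_case_study(small_cfg, with_bootstrap=True)
            report = run_workflow(study, seed=99)
            runs.append((derived_hash(study), report.outputs_for("test/bootstrap")["p_value"],
                         [(s.plugin_id, s.subject, s.status) for s in report.stages]))
        assert runs[0] == runs[1]

    def test_progress_reaches_one_and_counts_units(self, small_cfg):
        from timebench.casestudy import build_case_study

        study = build_case_study(small_cfg)
        seen = []
        report = run_workflow(study, progress=lambda done, total: seen.append((done, total)))
        assert report.completed_fraction == 1.0
        assert seen[-1] == (report.total_units, report.total_units)
        assert report.total_units == len(study.workflow) * len(study.subjects)

    def test_locked_study_rejects_run(self, toy_study):
        toy_study.locked = True
        with pytest.raises(LockedStudyError):
            run_workflow(toy_study)

    def test_invalid_selection_rejected(self, toy_study):
        with pytest.raises(IndexError):
            run_workflow(toy_study, subject_selection=[5])
        with pytest.raises(IndexError):
            run_workflow(toy_study, plugin_selection=[0])

    def test_rerun_overwrites_derived_outputs(self, small_cfg):
        from timebench.casestudy import build_case_study

        study = build_case_study(small_cfg)
        run_workflow(study)
        h1 = derived_hash(study)
        run_workflow(study)  # identical rerun replaces stage outputs in place
        assert derived_hash(study) == h1


def _failing_registry():
    reg = PluginRegistry()

    def declare_touch():
        return PluginSpec(
            plugin_id="test/touch", category="test",
            settings_schema={"value": SettingSpec("float", default=1.0)},
        )

    def touch(study, subject, settings, ctx):
        subject.substructures.setdefault("eyetracking", Modality()).derived[
            "touched"
        ] = settings["value"]

    def declare_fail():
        return PluginSpec(plugin_id="test/fail_on_s2", category="test")

    def fail(study, subject, settings, ctx):
        if subject.name == "s2":
            raise RuntimeError("boom")

    reg.register(declare_touch, dict, touch)
    reg.register(declare_fail, dict, fail)
    return reg


def _two_subject_study():
    study = Study(name="two")
    for name in ("s1", "s2", "s3"):
        study.add_subject(Subject(name=name))
    return study


class TestErrorPolicy:
    def test_failure_reports_plugin_subject_pair(self):
        reg = _failing_registry()
        study = _two_subject_study()
        study.append_stage(instantiate("test/fail_on_s2", registry=reg))
        report = run_workflow(study, registry=reg, on_error="continue")
        assert report.failures == [("test/fail_on_s2", "s2")]
        assert "boom" in [s.message for s in report.stages if s.status == "failed"][0]

    def test_abort_policy_stops_at_first_failure(self):
        reg = _failing_registry()
        study = _two_subject_study()
        study.append_stage(instantiate("test/fail_on_s2", registry=reg))
        study.append_stage(instantiate("test/touch", registry=reg))
        report = run_workflow(study, registry=reg, on_error="abort")
        assert not report.ok
        # second stage never ran
        assert all(s.plugin_id != "test/touch" for s in report.stages)

    def test_continue_policy_preserves_prior_stage_outputs(self):
        reg = _failing_registry()
        study = _two_subject_study()
        study.append_stage(instantiate("test/touch", registry=reg, overrides={"value": 7.0}))
        study.append_stage(instantiate("test/fail_on_s2", registry=reg))
        report = run_workflow(study, registry=reg, on_error="continue")
        assert report.failures == [("test/fail_on_s2", "s2")]
        for name in ("s1", "s2", "s3"):
            assert study.subject(name).substructures["eyetracking"].derived["touched"] == 7.0


class TestProvenance:
    def test_one_record_per_executed_stage(self, toy_study):
        toy_study.append_stage(_stage("core/interpolate_gaps"))
        toy_study.append_stage(_stage("core/filter_moving_average"))
        run_workflow(toy_study, seed=4)
        assert [p.plugin_id for p in toy_study.provenance] == [
            "core/interpolate_gaps",
            "core/filter_moving_average",
        ]
        rec = toy_study.provenance[0]
        assert rec.subjects == ["s1"]
        assert rec.input_hash != rec.output_hash  # interpolation changed data

    def test_identical_rerun_appends_identical_record_except_timestamp(self, toy_study):
        toy_study.append_stage(_stage("core/filter_moving_average"))
        first, second = copy.deepcopy(toy_study), copy.deepcopy(toy_study)
        run_workflow(first, seed=4)
        run_workflow(second, seed=4)
        da, db = first.provenance[-1].to_dict(), second.provenance[-1].to_dict()
        da.pop("timestamp"), db.pop("timestamp")
        assert da == db

    def test_run_snapshots_plugin_sources_into_study(self, toy_study):
        toy_study.append_stage(_stage("core/interpolate_gaps"))
        run_workflow(toy_study)
        assert "core/interpolate_gaps" in toy_study.plugin_sources
        assert "def interpolate_gaps" in toy_study.plugin_sources["core/interpolate_gaps"]


def test_derive_seed_is_stable_and_bounded():
    s = derive_seed(1, "core/x", "subj")
    assert s == derive_seed(1, "core/x", "subj")
    assert 0 <= s < 2**31
    assert derive_seed(1, "core/x", "other") != s
    assert derive_seed(2, "core/x", "subj") != s
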