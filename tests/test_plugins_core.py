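"""Hand-computed oracles and invariants for the five processing stages."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from timebench import (
    ColumnMap,
    Event,
    EventList,
    Modality,
    Study,
    Subject,
    extract_event_related,
    interpolate_gaps,
    modify_events,
    moving_filter,
    read_columnar_file,
    summarize_per_subject,
)
from timebench.model import EventRelatedData, ConditionEpochs

from conftest import make_channel

NAN = float("nan")


# ---------------------------------------------------------------------------
# stage 1: columnar reader
# ---------------------------------------------------------------------------


class TestReadColumnarFile:
    CMAP = ColumnMap(
        timestamp_column="t",
        channels={"pupil": "pupil"},
        event_column="ev",
        timestamp_unit="ms",
        missing_codes={"pupil": ["-1"]},
    )

    def test_header_only_file_yields_empty_modality(self):
        mod = read_columnar_file("t\tpupil\tev\n", self.CMAP)
        assert mod.channels["pupil"].n_samples == 0
        assert len(mod.events) == 0

    def test_five_row_file_hand_parse(self):
        text = (
            "t\tpupil\tev\n"
            "0\t3.0\t\n20\t3.1\t\n40\t3.2\tstim\n60\t-1\t\n80\t3.4\t\n"
        )
        mod = read_columnar_file(text, self.CMAP)
        ch = mod.channels["pupil"]
        assert ch.n_samples == 5
        assert ch.sample_rate == pytest.approx(50.0)
        assert ch.start_time == 0.0
        np.testing.assert_array_equal(ch.values, [3.0, 3.1, 3.2, np.nan, 3.4])
        assert [e.name for e in mod.events] == ["stim"]
        assert mod.events.events[0].time == pytest.approx(0.040)

    def test_missing_mapped_column_rejected(self):
        with pytest.raises(ValueError, match="pupil"):
            read_columnar_file("t\tother\tev\n0\t1\t\n", self.CMAP)

    def test_unparseable_timestamp_rejected(self):
        with pytest.raises(ValueError, match="timestamp"):
            read_columnar_file("t\tpupil\tev\nabc\t1\t\n", self.CMAP)

    def test_nonuniform_spacing_rejected(self):
        text = "t\tpupil\tev\n0\t1\t\n20\t1\t\n100\t1\t\n"
        with pytest.raises(ValueError, match="uniform"):
            read_columnar_file(text, self.CMAP)


# ---------------------------------------------------------------------------
# stage 2: event modification
# ---------------------------------------------------------------------------


class TestModifyEvents:
    def test_empty_rules_are_identity(self):
        events = EventList([Event("A", 0.0), Event("B", 1.0)])
        assert modify_events(events, []) == events

    def test_first_matching_rule_wins_and_unmatched_pass_through(self):
        events = EventList([Event("A", 0.0), Event("B", 1.0), Event("C", 2.0)])
        out = modify_events(events, [("A", "X"), ("B", "X")])
        assert out.names() == ["X", "X", "C"]
        np.testing.assert_array_equal(out.times(), events.times())
        assert len(out) == len(events)

    def test_wildcard_patterns_group_triggers_into_conditions(self):
        events = EventList([Event("stim_2x3", 0.0), Event("stim_12x17", 5.0)])
        out = modify_events(events, [("stim_2x*", "easy"), ("stim_12x*", "difficult")])
        assert out.names() == ["easy", "difficult"]


# ---------------------------------------------------------------------------
# stage 3: gap interpolation
# ---------------------------------------------------------------------------


class TestInterpolateGaps:
    def test_channel_without_missing_samples_is_identity(self):
        ch = make_channel([1.0, 2.0, 3.0])
        out = interpolate_gaps(ch, max_gap=5)
        np.testing.assert_array_equal(out.values, ch.values)

    def test_single_gap_linear_hand_value(self):
        out = interpolate_gaps(make_channel([1.0, NAN, 3.0]), max_gap=5, method="linear")
        np.testing.assert_allclose(out.values, [1.0, 2.0, 3.0])

    def test_gap_length_threshold_is_strict(self):
        base = [1.0] + [NAN] * 5 + [7.0]
        out5 = interpolate_gaps(make_channel(base), max_gap=5)
        assert np.isnan(out5.values[1:6]).all()  # length 5 not filled
        base4 = [1.0] + [NAN] * 4 + [6.0]
        out4 = interpolate_gaps(make_channel(base4), max_gap=5)
        np.testing.assert_allclose(out4.values, [1, 2, 3, 4, 5, 6])  # length 4 filled

    def test_max_jump_criterion_blocks_fill(self):
        out = interpolate_gaps(make_channel([0.0, NAN, 10.0]), max_gap=5, max_jump=5.0)
        assert np.isnan(out.values[1])
        out2 = interpolate_gaps(make_channel([0.0, NAN, 10.0]), max_gap=5, max_jump=10.0)
        assert out2.values[1] == pytest.approx(5.0)

    def test_valid_range_criterion_blocks_fill(self):
        ch = make_channel([0.0, NAN, 10.0])
        out = interpolate_gaps(ch, max_gap=5, valid_range=(0.0, 4.0))
        assert np.isnan(out.values[1])

    def test_edge_gaps_never_filled(self):
        out = interpolate_gaps(make_channel([NAN, 1.0, 2.0, NAN]), max_gap=5)
        assert np.isnan(out.values[0]) and np.isnan(out.values[3])

    def test_nearest_method(self):
        out = interpolate_gaps(
            make_channel([1.0, NAN, NAN, 10.0]), max_gap=5, method="nearest"
        )
        np.testing.assert_allclose(out.values, [1.0, 1.0, 10.0, 10.0])

    def test_invalid_method_and_range_rejected(self):
        with pytest.raises(ValueError, match="method"):
            interpolate_gaps(make_channel([1.0, NAN, 2.0]), 5, method="spline")
        with pytest.raises(ValueError, match="valid_range"):
            interpolate_gaps(make_channel([1.0, NAN, 2.0]), 5, valid_range=(2.0, 1.0))

    @given(
        slope=st.floats(-5, 5),
        intercept=st.floats(-10, 10),
        start=st.integers(1, 20),
        length=st.integers(1, 6),
    )
    def test_linear_interpolation_exact_on_linear_signal(
        self, slope, intercept, start, length
    ):
        n = 30
        line = intercept + slope * np.arange(n, dtype=float)
        values = line.copy()
        values[start : start + length] = np.nan
        out = interpolate_gaps(make_channel(values), max_gap=10, method="linear")
        np.testing.assert_allclose(out.values, line, atol=1e-9, rtol=1e-9)

    @given(
        values=st.lists(
            st.one_of(st.floats(-100, 100), st.just(NAN)), min_size=3, max_size=60
        ),
        max_gap=st.integers(1, 8),
    )
    def test_fill_never_modifies_originally_valid_samples(self, values, max_gap):
        values = np.asarray(values, float)
        if np.sum(~np.isnan(values)) < 2:
            return
        out = interpolate_gaps(make_channel(values), max_gap=max_gap)
        valid = ~np.isnan(values)
        assert np.array_equal(
            out.values[valid].view(np.uint64), values[valid].view(np.uint64)
        )


# ---------------------------------------------------------------------------
# stage 4: zero-phase moving filter
# ---------------------------------------------------------------------------


class TestMovingFilter:
    @pytest.mark.parametrize("statistic", ["mean", "median"])
    def test_constant_channel_is_fixed_point(self, statistic):
        ch = make_channel(np.full(20, 4.2))
        out = moving_filter(ch, halfwidth=3, statistic=statistic)
        np.testing.assert_allclose(out.values, ch.values)

    def test_median_hand_example(self):
        out = moving_filter(make_channel([0, 0, 10, 0, 0]), 1, "median")
        np.testing.assert_allclose(out.values, np.zeros(5))

    def test_mean_hand_example_with_edge_shrinkage(self):
        out = moving_filter(make_channel([0.0, 3.0, 6.0]), 1, "mean")
        np.testing.assert_allclose(out.values, [1.5, 3.0, 4.5])

    def test_all_missing_window_stays_missing(self):
        out = moving_filter(make_channel([NAN, NAN, NAN, 1.0]), 1, "mean")
        assert np.isnan(out.values[0])
        assert out.values[3] == pytest.approx(1.0)

    def test_negative_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            moving_filter(make_channel([1.0]), -1)

    @given(
        h=st.integers(1, 4),
        k=st.integers(1, 4),
        magnitude=st.floats(1, 1e6),
    )
    def test_median_removes_outlier_runs_up_to_halfwidth(self, h, k, magnitude):
        if k > h:
            return
        pad = 2 * h
        values = np.full(pad + k + pad, 1.0)
        values[pad : pad + k] = 1.0 + magnitude
        out = moving_filter(make_channel(values), h, "median")
        np.testing.assert_allclose(out.values, np.full(values.size, 1.0))

    @given(
        half=st.lists(st.floats(-10, 10), min_size=2, max_size=20),
        statistic=st.sampled_from(["mean", "median"]),
        h=st.integers(0, 4),
    )
    def test_zero_phase_symmetry_preserved(self, half, statistic, h):
        values = np.asarray(half + half[::-1], float)  # symmetric about centre
        out = moving_filter(make_channel(values), h, statistic).values
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)


# ---------------------------------------------------------------------------
# stage 5: event-related extraction
# ---------------------------------------------------------------------------


def _extract(ch, events, **kw):
    defaults = dict(
        conditions=["c"],
        trial_window=(0.0, 1.0),
        baseline_window=(0.0, 0.5),
        measure_window=(0.0, 1.0),
        measures=["mean", "median", "min", "max", "latency_to_min", "latency_to_max", "range"],
    )
    defaults.update(kw)
    return extract_event_related(ch, events, **defaults)


class TestExtractEventRelated:
    def test_zero_channel_yields_zero_measures(self):
        ch = make_channel(np.zeros(100), sample_rate=10.0)
        res = _extract(ch, EventList([Event("c", 2.0)]))
        trial = res.data.conditions["c"].matrix[0]
        np.testing.assert_array_equal(trial, np.zeros(10))
        vals = dict(zip(res.table.df["measure"], res.table.df["value"]))
        for m in ("mean", "median", "min", "max", "range"):
            assert vals[m] == 0.0

    def test_hand_computed_trial_measures(self):
        ch = make_channel(np.arange(1.0, 11.0), sample_rate=10.0)
        res = _extract(ch, EventList([Event("c", 0.0)]))
        corrected = res.data.conditions["c"].matrix[0]
        np.testing.assert_allclose(corrected, np.arange(-2.0, 8.0))  # baseline mean 3
        vals = dict(zip(res.table.df["measure"], res.table.df["value"]))
        assert vals["max"] == pytest.approx(7.0)
        assert vals["latency_to_max"] == pytest.approx(0.9)
        assert vals["min"] == pytest.approx(-2.0)
        assert vals["latency_to_min"] == pytest.approx(0.0)
        assert vals["range"] == pytest.approx(9.0)
        assert vals["mean"] == pytest.approx(2.5)
        assert vals["median"] == pytest.approx(2.5)

    def test_trials_extending_past_recording_are_dropped_and_counted(self):
        ch = make_channel(np.zeros(100), sample_rate=10.0)  # 10 s
        events = EventList([Event("c", 1.0), Event("c", 8.9), Event("other", 2.0)])
        res = _extract(ch, events)
        assert res.data.conditions["c"].matrix.shape[0] == 2
        assert res.n_dropped == 0
        res_long = _extract(
            ch, events, trial_window=(0.0, 2.0), measure_window=(0.0, 2.0)
        )
        assert res_long.data.conditions["c"].matrix.shape[0] == 1
        assert res_long.n_dropped == 1

    def test_trial_count_equals_matching_events_inside_recording(self):
        rng = np.random.default_rng(3)
        ch = make_channel(rng.normal(size=500), sample_rate=50.0)  # 10 s
        times = rng.uniform(0, 10, size=12)
        events = EventList()
        events.extend([Event("c", float(t)) for t in times])
        res = _extract(ch, events, trial_window=(0.0, 1.0))
        expected = sum(1 for t in times if np.ceil(t * 50 - 1e-9) + 50 <= 500)
        assert res.data.conditions["c"].matrix.shape[0] == expected
        assert res.n_dropped == len(times) - expected

    def test_baseline_mean_is_zero_after_correction(self):
        rng = np.random.default_rng(7)
        values = rng.normal(3.5, 0.3, size=1000)
        values[rng.integers(0, 1000, 40)] = np.nan
        ch = make_channel(values, sample_rate=50.0)
        events = EventList([Event("c", t) for t in (1.0, 5.0, 9.0)])
        res = _extract(
            ch,
            events,
            trial_window=(0.0, 4.0),
            baseline_window=(0.0, 2.0),
            measure_window=(3.0, 4.0),
        )
        scale = np.nanmax(np.abs(res.data.conditions["c"].matrix))
        for trial in res.data.conditions["c"].matrix:
            baseline = trial[:100]
            assert abs(np.nanmean(baseline)) <= 1e-9 * max(scale, 1.0)

    def test_no_matching_event_rejected(self):
        ch = make_channel(np.zeros(100), sample_rate=10.0)
        with pytest.raises(ValueError, match="no event matches"):
            _extract(ch, EventList([Event("other", 1.0)]))

    def test_window_ordering_enforced(self):
        ch = make_channel(np.zeros(100), sample_rate=10.0)
        events = EventList([Event("c", 1.0)])
        with pytest.raises(ValueError, match="baseline"):
            _extract(ch, events, baseline_window=(-1.0, 0.5))
        with pytest.raises(ValueError, match="measure"):
            _extract(ch, events, measure_window=(0.5, 2.0))

    def test_unknown_measure_rejected(self):
        ch = make_channel(np.zeros(100), sample_rate=10.0)
        with pytest.raises(ValueError, match="unknown measure"):
            _extract(ch, EventList([Event("c", 1.0)]), measures=["variance"])

    def test_confidence_band_brackets_the_mean(self):
        rng = np.random.default_rng(1)
        ch = make_channel(rng.normal(size=2000), sample_rate=50.0)
        events = EventList([Event("c", float(t)) for t in np.arange(0.5, 30.0, 2.0)])
        res = _extract(
            ch, events, trial_window=(0.0, 1.0), baseline_window=(0.0, 0.5),
            measure_window=(0.5, 1.0),
        )
        c = res.curves.curves["c"]
        assert np.all(c["lo"] <= c["mean"]) and np.all(c["mean"] <= c["hi"])


class TestSummarizePerSubject:
    @staticmethod
    def _study_with_trialvalues(values_by_subject):
        study = Study(name="s")
        for name, per_cond in values_by_subject.items():
            mod = Modality()
            mod.derived["event_related"] = EventRelatedData(
                conditions={
                    cond: ConditionEpochs(
                        matrix=np.zeros((len(tv), 1)),
                        onsets=np.zeros(len(tv)),
                        trialvalues=np.asarray(tv, float),
                    )
                    for cond, tv in per_cond.items()
                },
                sample_rate=50.0,
                trial_window=(0.0, 1.0),
                measure="mean",
            )
            study.add_subject(Subject(name=name, substructures={"eyetracking": mod}))
        return study

    def test_single_trial_means_equal_trial_values(self):
        study = self._study_with_trialvalues({"s1": {"easy": [2.0], "difficult": [5.0]}})
        m = summarize_per_subject(study, ["easy", "difficult"])
        assert m.loc["easy", "s1"] == 2.0
        assert m.loc["difficult", "s1"] == 5.0

    def test_missing_ignoring_mean(self):
        study = self._study_with_trialvalues({"s1": {"easy": [1.0, 2.0, NAN]}})
        m = summarize_per_subject(study, ["easy"])
        assert m.loc["easy", "s1"] == pytest.approx(1.5)

    def test_condition_absent_for_all_subjects_rejected(self):
        study = self._study_with_trialvalues({"s1": {"easy": [1.0]}})
        with pytest.raises(ValueError, match="absent"):
            summarize_per_subject(study, ["easy", "no_such_condition"])
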