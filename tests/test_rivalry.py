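"""Keypress-stream segmentation and preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eyegaba as eg
from eyegaba.exceptions import MalformedInputError, ParameterError
from eyegaba.rivalry import LEFT_EYE, MISSING, MIXED, RIGHT_EYE, PerceptPhase

from conftest import make_run
from _oracles import oracle_preprocess


def phases_tuple(pp):
    return [(p.onset, p.offset, p.label, p.censored) for p in pp]


class TestSegmentStream:
    def test_empty_stream_gives_no_phases(self):
        assert eg.segment_stream(make_run([])) == []

    def test_constant_report_spans_whole_run(self):
        run = make_run([(0.0, "cw")], duration=180.0, cw_eye="right")
        phases = eg.segment_stream(run)
        assert phases_tuple(phases) == [(0.0, 180.0, RIGHT_EYE, True)]

    def test_three_event_trace(self):
        run = make_run([(0, "cw"), (5, "none"), (6, "ccw")], duration=10.0, cw_eye="right")
        assert phases_tuple(eg.segment_stream(run)) == [
            (0.0, 5.0, RIGHT_EYE, False),
            (5.0, 6.0, MISSING, False),
            (6.0, 10.0, LEFT_EYE, True),
        ]

    def test_eye_mapping_flips_with_cw_eye(self):
        run = make_run([(0, "cw")], cw_eye="left")
        assert eg.segment_stream(run)[0].label == LEFT_EYE

    def test_time_before_first_event_is_missing(self):
        run = make_run([(2.0, "mixed")], duration=4.0)
        assert phases_tuple(eg.segment_stream(run)) == [
            (0.0, 2.0, MISSING, False),
            (2.0, 4.0, MIXED, True),
        ]

    def test_repeated_same_state_coalesces(self):
        run = make_run([(0, "cw"), (3, "cw"), (5, "ccw")], duration=8.0, cw_eye="right")
        labels = [p.label for p in eg.segment_stream(run)]
        assert labels == [RIGHT_EYE, LEFT_EYE]

    @pytest.mark.parametrize(
        "events",
        [
            [(5, "cw"), (2, "ccw")],  # unsorted
            [(1, "cw"), (1, "ccw")],  # duplicate time
            [(0, "up")],  # unknown state
            [(0, "cw"), (11, "ccw")],  # beyond run end
        ],
    )
    def test_malformed_streams_rejected(self, events):
        with pytest.raises(MalformedInputError):
            eg.segment_stream(make_run(events, duration=10.0))


class TestPreprocess:
    def test_missing_assigned_to_subsequent_percept(self):
        raw = [
            PerceptPhase(0, 5, RIGHT_EYE),
            PerceptPhase(5, 6, MISSING),
            PerceptPhase(6, 10, LEFT_EYE, censored=True),
        ]
        pp = eg.preprocess_phases(raw)
        assert phases_tuple(pp.phases) == [
            (0, 5, RIGHT_EYE, False),
            (5, 10, LEFT_EYE, True),
        ]
        assert pp.accounting.removed_short_time == 0
        assert pp.accounting.residual_missing_time == 0

    def test_short_response_between_same_label_merges(self):
        raw = [
            PerceptPhase(0, 4, LEFT_EYE),
            PerceptPhase(4, 4.15, RIGHT_EYE),
            PerceptPhase(4.15, 9, LEFT_EYE, censored=True),
        ]
        pp = eg.preprocess_phases(raw)
        assert phases_tuple(pp.phases) == [(0, 9, LEFT_EYE, True)]
        assert pp.accounting.removed_short_count == 1

    def test_clean_phases_pass_through(self):
        raw = [
            PerceptPhase(0, 3, LEFT_EYE),
            PerceptPhase(3, 7, RIGHT_EYE),
            PerceptPhase(7, 9, LEFT_EYE, censored=True),
        ]
        pp = eg.preprocess_phases(raw)
        assert phases_tuple(pp.phases) == phases_tuple(raw)

    def test_mixed_time_goes_to_accounting(self):
        raw = [
            PerceptPhase(0, 3, LEFT_EYE),
            PerceptPhase(3, 5, MIXED),
            PerceptPhase(5, 9, RIGHT_EYE, censored=True),
        ]
        pp = eg.preprocess_phases(raw)
        assert [p.label for p in pp.phases] == [LEFT_EYE, RIGHT_EYE]
        assert pp.accounting.mixed_time == pytest.approx(2.0)

    def test_negative_min_duration_rejected(self):
        with pytest.raises(ParameterError):
            eg.preprocess_phases([], min_duration=-0.1)

    def test_idempotent(self):
        run = make_run(
            [(0.3, "cw"), (2, "none"), (2.5, "ccw"), (2.6, "cw"), (4, "mixed"), (5, "ccw")],
            duration=8.0,
        )
        once = eg.preprocess_phases(eg.segment_stream(run))
        twice = eg.preprocess_phases(list(once.phases))
        assert phases_tuple(twice.phases) == phases_tuple(once.phases)
        assert twice.accounting.removed_short_count == 0


# random event streams: up to 6 events on a 0.1 s grid in a 3 s run
event_streams = st.lists(
    st.tuples(st.integers(0, 29), st.sampled_from(["cw", "ccw", "mixed", "none"])),
    max_size=6,
    unique_by=lambda ev: ev[0],
).map(lambda evs: sorted(((t / 10.0, s) for t, s in evs)))


class TestStreamProperties:
    @settings(max_examples=300, derandomize=True)
    @given(events=event_streams, cw_eye=st.sampled_from(["left", "right"]))
    def test_segmentation_partitions_run(self, events, cw_eye):
        run = make_run(events, duration=3.0, cw_eye=cw_eye)
        phases = eg.segment_stream(run)
        if not events:
            assert phases == []
            return
        assert phases[0].onset == 0.0
        assert phases[-1].offset == 3.0
        assert phases[-1].censored
        for a, b in zip(phases, phases[1:]):
            assert a.offset == b.onset
            assert a.label != b.label

    @settings(max_examples=300, derandomize=True)
    @given(events=event_streams, cw_eye=st.sampled_from(["left", "right"]))
    def test_time_conservation(self, events, cw_eye):
        """Kept + mixed + residual missing time partitions the whole run."""
        run = make_run(events, duration=3.0, cw_eye=cw_eye)
        pp = eg.preprocess_phases(eg.segment_stream(run))
        if not events:
            return
        acc = pp.accounting
        total = acc.kept_eye_time + acc.mixed_time + acc.residual_missing_time
        assert total == pytest.approx(3.0, abs=1e-9)
        # initial missing stretch = time until the first informative report
        first_report = next((t for t, s in events if s != "none"), 3.0)
        assert acc.leading_missing_time == pytest.approx(first_report, abs=1e-9)

    @settings(max_examples=300, derandomize=True)
    @given(events=event_streams, cw_eye=st.sampled_from(["left", "right"]))
    def test_matches_brute_force_oracle(self, events, cw_eye):
        run = make_run(events, duration=3.0, cw_eye=cw_eye)
        pp = eg.preprocess_phases(eg.segment_stream(run))
        ora_eye, ora_mixed, ora_missing = oracle_preprocess(events, 3.0, cw_eye)
        got = [(p.onset, p.offset, p.label, p.censored) for p in pp.phases]
        assert len(got) == len(ora_eye)
        for g, o in zip(got, ora_eye):
            assert g[0] == pytest.approx(o[0], abs=1e-9)
            assert g[1] == pytest.approx(o[1], abs=1e-9)
            assert g[2] == o[2]
            assert g[3] == o[3]
        assert pp.accounting.mixed_time == pytest.approx(ora_mixed, abs=1e-9)
        assert pp.accounting.residual_missing_time == pytest.approx(ora_missing, abs=1e-9)


class TestPooling:
    def test_pooling_concatenates_across_runs(self):
        pp1 = eg.preprocess_phases(
            [PerceptPhase(0, 2, LEFT_EYE), PerceptPhase(2, 6, RIGHT_EYE),
             PerceptPhase(6, 9, LEFT_EYE)]
        )
        pp2 = eg.preprocess_phases([PerceptPhase(0, 3, LEFT_EYE)])
        pooled = eg.pool_durations([pp1, pp2])
        assert sorted(pooled.left) == [2.0, 3.0, 3.0]
        assert list(pooled.right) == [4.0]

    def test_censored_excluded_by_default(self):
        pp = eg.preprocess_phases(
            [PerceptPhase(0, 2, LEFT_EYE), PerceptPhase(2, 5, RIGHT_EYE, censored=True)]
        )
        assert eg.pool_durations([pp]).right.size == 0
        assert eg.pool_durations([pp], include_censored=True).right.size == 1

    def test_empty_sample_flagged(self):
        pp = eg.preprocess_phases([PerceptPhase(0, 2, LEFT_EYE)])
        pooled = eg.pool_durations([pp])
        with pytest.raises(eg.exceptions.EmptySampleError):
            pooled.sample("right")


class TestNormalize:
    def test_scaling(self):
        assert list(eg.normalize_pooled_durations([2.0, 4.0], 2.0)) == [1.0, 2.0]

    def test_de_sample_median_is_one(self, rng):
        sample = rng.gamma(4.0, 0.6, size=501)
        norm = eg.normalize_pooled_durations(sample, float(np.median(sample)))
        assert np.median(norm) == pytest.approx(1.0)

    def test_invalid_median_rejected(self):
        with pytest.raises(ParameterError):
            eg.normalize_pooled_durations([1.0], 0.0)
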