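"""D-Counter, fixed threshold, event extraction and event matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eagdc import (
    CounterTrace,
    DCounterParams,
    DetectionEvents,
    FixedThresholdParams,
    ParameterError,
    SignalError,
    Trace,
    d_counter_stream,
    d_counter_window,
    extract_events,
    fixed_threshold,
    match_events,
)


def d_counter_reference(window, th):
    """Literal, loop-by-loop transcription of the dropping-counter rule.

    Independent oracle: walks the window sample by sample, counts drops
    below the first value, tracks the deepest drop (starting at 0), and
    zeroes the count when that deepest drop never reaches th.
    """
    count = 0
    delta_max = 0.0
    ref = window[0]
    for v in window:
        delta = v - ref
        if delta < 0:
            count += 1
            if delta < delta_max:
                delta_max = delta
    if delta_max > th:
        count = 0
    return count


class TestDCounterWindow:
    @pytest.mark.parametrize(
        "window, th, expected",
        [
            ([0.0, 0.0, 0.0], -0.1, 0),            # no drops at all
            ([0.0, -0.2, -0.6], -0.5, 2),          # two drops, deepest passes th
            ([0.0, -0.2, -0.6], -0.7, 0),          # deepest drop too shallow: reset
            ([0.0, -0.3, -0.6, -0.9], -0.5, 3),    # strictly decreasing: w-1
        ],
    )
    def test_hand_derived_counts(self, window, th, expected):
        assert d_counter_window(window, th) == expected

    def test_rejects_windows_shorter_than_two(self):
        with pytest.raises(ParameterError):
            d_counter_window([0.0], -0.5)

    @given(
        window=st.lists(st.floats(-3, 3, allow_nan=False), min_size=2, max_size=30),
        th=st.floats(-2.0, -0.01),
    )
    @settings(max_examples=200, deadline=None)
    def test_count_bounded_by_window_length(self, window, th):
        c = d_counter_window(window, th)
        assert 0 <= c <= len(window) - 1

    def test_full_count_requires_all_drops_and_depth(self):
        # w-1 attained iff every non-reference sample is below the reference
        # and the deepest drop reaches th
        assert d_counter_window([0, -0.1, -0.2, -0.8], -0.5) == 3
        assert d_counter_window([0, -0.1, 0.2, -0.8], -0.5) == 2
        assert d_counter_window([0, -0.1, -0.2, -0.4], -0.5) == 0


class TestDCounterStream:
    def test_constant_trace_counts_all_zero(self):
        ct = d_counter_stream(Trace(np.zeros(100), 100.0), DCounterParams(0.1, -0.5, 100.0))
        assert len(ct) == 91
        assert not ct.counts.any()

    def test_short_trace_windows_follow_reset_rule(self, short_trace):
        # [0,-0.2,-0.6] drops twice and reaches -0.6 <= th -> 2;
        # [-0.2,-0.6,-0.6] drops twice but only to -0.4 > th -> reset to 0
        ct = d_counter_stream(short_trace, DCounterParams(0.03, -0.5, 100.0))
        np.testing.assert_array_equal(ct.counts, [2, 0])

    def test_matches_literal_reference_on_random_traces(self, rng):
        for w in (3, 10, 20):
            params = DCounterParams(w / 100.0, -0.3, 100.0)
            for _ in range(20):
                x = rng.normal(0, 0.4, 200)
                ct = d_counter_stream(Trace(x, 100.0), params)
                expected = [
                    d_counter_reference(x[i:i + w], params.th)
                    for i in range(x.size - w + 1)
                ]
                np.testing.assert_array_equal(ct.counts, expected)

    @given(offset=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariance(self, offset):
        x = np.random.default_rng(42).normal(0, 0.5, 120)
        params = DCounterParams(0.1, -0.4, 100.0)
        a = d_counter_stream(Trace(x, 100.0), params).counts
        b = d_counter_stream(Trace(x + offset, 100.0), params).counts
        np.testing.assert_array_equal(a, b)

    def test_not_invariant_to_amplitude_scaling(self):
        # halving a drop that straddles th flips the reset decision
        x = np.array([0.0, -0.3, -0.6, -0.6, 0.0])
        params = DCounterParams(0.03, -0.5, 100.0)
        full = d_counter_stream(Trace(x, 100.0), params).counts
        halved = d_counter_stream(Trace(0.5 * x, 100.0), params).counts
        assert not np.array_equal(full, halved)

    def test_deeper_threshold_never_increases_counts(self, rng):
        x = rng.normal(0, 0.4, 300)
        shallow = d_counter_stream(Trace(x, 100.0), DCounterParams(0.1, -0.2, 100.0)).counts
        deep = d_counter_stream(Trace(x, 100.0), DCounterParams(0.1, -0.6, 100.0)).counts
        assert (deep <= shallow).all()

    def test_not_time_reversal_symmetric(self, rng):
        # the detector is drop-specific: reversing time turns drops into rises
        x = np.r_[np.zeros(20), np.linspace(0, -1, 20), np.zeros(20)]
        params = DCounterParams(0.1, -0.5, 100.0)
        fwd = d_counter_stream(Trace(x, 100.0), params).counts
        rev = d_counter_stream(Trace(x[::-1].copy(), 100.0), params).counts
        assert not np.array_equal(fwd, rev[::-1])

    def test_trace_shorter_than_window_is_an_error(self):
        with pytest.raises(SignalError):
            d_counter_stream(Trace(np.zeros(5), 100.0), DCounterParams(0.1, -0.5, 100.0))

    def test_rejects_nonnegative_threshold(self):
        with pytest.raises(ParameterError):
            DCounterParams(0.1, 0.0, 100.0)


class TestFixedThreshold:
    @pytest.mark.parametrize(
        "samples, th, expected",
        [
            ([-0.6, 0.0, -0.4], -0.5, [1, 0, 0]),
            ([0.0, 0.0, 0.0], -0.5, [0, 0, 0]),
            ([-0.5, -0.5], -0.5, [0, 0]),  # strict <: equality does not trigger
        ],
    )
    def test_elementwise_comparison(self, samples, th, expected):
        out = fixed_threshold(Trace(samples, 100.0), FixedThresholdParams(th))
        np.testing.assert_array_equal(out.samples, expected)

    def test_commutes_with_time_reversal(self, rng):
        x = rng.normal(0, 0.5, 200)
        params = FixedThresholdParams(-0.4)
        fwd = fixed_threshold(Trace(x, 100.0), params).samples
        rev = fixed_threshold(Trace(x[::-1].copy(), 100.0), params).samples
        np.testing.assert_array_equal(fwd, rev[::-1])


class TestExtractEvents:
    def _counter(self, counts, fs=100.0, w=10):
        return CounterTrace(np.asarray(counts), fs, w=w)

    def test_all_zero_counts_give_no_events(self):
        ev = extract_events(self._counter(np.zeros(50, dtype=int)), c_min=5)
        assert len(ev) == 0

    def test_two_runs_without_merging(self):
        ev = extract_events(
            self._counter([0, 5, 6, 0, 0, 0, 7, 0]), c_min=5, merge_gap_s=0.0
        )
        assert len(ev) == 2

    def test_close_runs_merge_within_gap(self):
        ev = extract_events(
            self._counter([0, 5, 6, 0, 0, 0, 7, 0]), c_min=5, merge_gap_s=0.1
        )
        assert len(ev) == 1  # 3-sample gap = 0.03 s < 0.1 s

    def test_onset_is_first_reference_index_of_run(self):
        ev = extract_events(self._counter([0, 0, 9, 9, 0]), c_min=5)
        assert ev.events[0][0] == pytest.approx(0.02)

    def test_c_min_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            extract_events(self._counter([0, 1, 0], w=10), c_min=10)
        with pytest.raises(ParameterError):
            extract_events(self._counter([0, 1, 0], w=10), c_min=0)


class TestMatchEvents:
    def _events(self, onsets, dur=0.2):
        return DetectionEvents(tuple((t, t + dur) for t in onsets), c_min=5, merge_gap_s=0.1)

    def test_exact_onsets_all_hit(self):
        stim = np.array([1.0, 3.0, 5.0])
        assert match_events(self._events(stim), stim, tol_s=0.5) == (3, 0, 0)

    def test_no_events_all_missed(self):
        ev = DetectionEvents((), c_min=5, merge_gap_s=0.1)
        assert match_events(ev, np.array([1.0, 2.0]), tol_s=0.5) == (0, 2, 0)

    def test_spurious_event_counts_as_false_alarm(self):
        ev = self._events([1.1, 9.0])
        assert match_events(ev, np.array([1.0]), tol_s=0.5) == (1, 0, 1)

    def test_event_before_onset_cannot_match(self):
        ev = self._events([0.9])
        assert match_events(ev, np.array([1.0]), tol_s=0.5) == (0, 1, 1)

    def test_one_event_matches_at_most_one_stimulus(self):
        ev = self._events([1.05])
        assert match_events(ev, np.array([1.0, 1.2]), tol_s=0.5) == (1, 1, 0)
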