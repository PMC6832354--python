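"""Odour-response detectors: the D-Counter and the fixed-threshold baseline.

The D-Counter ("dropping counter") slides a short window over the signal,
takes the first sample of each window as the reference, and counts how many
of the remaining samples lie below it.  The count is kept only when the
deepest drop in the window exceeds a relative depth threshold ``th``
(a negative voltage); otherwise it is reset to zero.  Because only
*differences* within the window are examined, the detector is immune to
baseline drift — the failure mode of an absolute (fixed) voltage threshold.

Also here: conversion of a counter trace into discrete detection events and
a greedy scorer matching events to ground-truth stimulus onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .signal_core import ParameterError, SignalError, Trace

__all__ = [
    "DCounterParams",
    "CounterTrace",
    "FixedThresholdParams",
    "DetectionEvents",
    "d_counter_window",
    "d_counter_stream",
    "fixed_threshold",
    "extract_events",
    "match_events",
]


@dataclass(frozen=True)
class DCounterParams:
    """D-Counter parameters.

    Parameters
    ----------
    s_win : float
        Window length in seconds; sets the detector latency, since the count
        attributed to a window's reference sample is only available once the
        whole window has been observed.
    th : float
        Relative depth threshold in mV, strictly negative: a window's count
        survives only if some sample sits more than ``|th|`` below the
        window's first sample.  A zero or positive ``th`` would reset every
        window (the deepest-drop tracker starts at 0), so it is rejected.
    fs : float
        Sampling rate in Hz of the traces this parameter set applies to.
    """

    s_win: float
    th: float
    fs: float

    def __post_init__(self):
        if not (np.isfinite(self.s_win) and self.s_win > 0):
            raise ParameterError(f"s_win must be positive, got {self.s_win}")
        if not (np.isfinite(self.th) and self.th < 0):
            raise ParameterError(f"th must be strictly negative (relative depth, mV), got {self.th}")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.w < 2:
            raise ParameterError(
                f"window of {self.w} sample(s) (s_win={self.s_win}s at fs={self.fs}Hz); need >= 2"
            )

    @property
    def w(self) -> int:
        """Window length in samples, round(s_win * fs)."""
        return int(round(self.s_win * self.fs))


@dataclass(frozen=True)
class CounterTrace:
    """Integer D-Counter output, one count per window reference index.

    ``counts[k]`` belongs to the window starting at input sample
    ``alignment[k]`` (stride 1, so alignment is simply 0..n-w), and is
    causally available once sample ``alignment[k] + w - 1`` has arrived.
    """

    counts: np.ndarray
    fs: float
    w: int
    t0: float = 0.0
    alignment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if self.alignment is None:
            object.__setattr__(self, "alignment", np.arange(counts.size))

    def __len__(self) -> int:
        return self.counts.size

    @property
    def times(self) -> np.ndarray:
        """Time of each count's reference sample."""
        return self.t0 + self.alignment / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times, "count": self.counts})


@dataclass(frozen=True)
class FixedThresholdParams:
    """Absolute voltage threshold (mV, negative) for the baseline detector."""

    th_abs: float

    def __post_init__(self):
        if not (np.isfinite(self.th_abs) and self.th_abs < 0):
            raise ParameterError(f"th_abs must be negative (mV), got {self.th_abs}")


def d_counter_window(window, th: float) -> int:
    """Count of samples dropping below the window's first (reference) sample.

    Each sample ``window[i]`` with ``window[i] - window[0] < 0`` increments
    the count; the most negative such difference is tracked (initialised at
    0), and if it never reaches ``th`` the count is reset to 0.  The result
    lies in ``[0, len(window) - 1]``: the reference sample itself can never
    count.
    """

    w = np.asarray(window, dtype=np.float64)
    if w.size < 2:
        raise ParameterError(f"window needs at least 2 samples, got {w.size}")
    if not np.all(np.isfinite(w)):
        raise SignalError("non-finite sample in window")
    delta = w - w[0]
    count = int(np.count_nonzero(delta < 0.0))
    delta_max = min(0.0, float(delta.min()))
    if delta_max > th:
        count = 0
    return count


def d_counter_stream(trace: Trace, params: DCounterParams) -> CounterTrace:
    """Apply the D-Counter over every window of the trace (stride 1).

    ``counts[n]`` is :func:`d_counter_window` on ``trace[n : n + w]``; the
    output has ``len(trace) - w + 1`` entries.  Vectorised, but exactly
    equivalent to evaluating each window independently.
    """

    x = trace.samples
    w = params.w
    if x.size < w:
        raise SignalError(f"trace of {x.size} samples is shorter than one window ({w})")
    windows = sliding_window_view(x, w)
    delta = windows - windows[:, :1]
    counts = np.count_nonzero(delta < 0.0, axis=1).astype(np.int64)
    delta_max = np.minimum(delta.min(axis=1), 0.0)
    counts[delta_max > params.th] = 0
    return CounterTrace(counts, trace.fs, w, t0=trace.t0)


def fixed_threshold(trace: Trace, params: FixedThresholdParams) -> Trace:
    """Baseline detector: 1 wherever the voltage is strictly below ``th_abs``.

    Output is a binary trace with the same length, rate and start time.
    Being an absolute comparison, it is defeated by baseline drift of the
    same order as the threshold.
    """

    if not isinstance(params, FixedThresholdParams):
        params = FixedThresholdParams(params)
    trig = (trace.samples < params.th_abs).astype(np.float64)
    return Trace(trig, trace.fs, trace.t0)


@dataclass(frozen=True)
class DetectionEvents:
    """Discrete detected response intervals, sorted and non-overlapping."""

    events: tuple  # of (onset_s, offset_s)
    c_min: int
    merge_gap_s: float

    def __post_init__(self):
        evs = tuple((float(a), float(b)) for a, b in self.events)
        for a, b in evs:
            if not a < b:
                raise ParameterError(f"event onset {a} must precede offset {b}")
        for (_, b0), (a1, _) in zip(evs, evs[1:]):
            if a1 < b0:
                raise ParameterError("events must be sorted and non-overlapping")
        object.__setattr__(self, "events", evs)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([a for a, _ in self.events])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.events), columns=["onset_s", "offset_s"])


def extract_events(counter: CounterTrace, c_min: int, merge_gap_s: float = 0.1) -> DetectionEvents:
    """Turn a counter trace into discrete events.

    Maximal runs with ``counts >= c_min`` become events; the onset is the
    time of the run's first reference index, the offset one sample past its
    last.  Events separated by less than ``merge_gap_s`` are merged — a
    refractory interval that keeps a single flickering response from
    splitting, chosen shorter than any inter-stimulus interval of interest.
    """

    if not (1 <= c_min <= counter.w - 1):
        raise ParameterError(f"c_min must lie in [1, w-1] = [1, {counter.w - 1}], got {c_min}")
    if merge_gap_s < 0:
        raise ParameterError(f"merge_gap_s must be >= 0, got {merge_gap_s}")

    active = counter.counts >= c_min
    # run boundaries on the boolean mask
    edges = np.diff(active.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)  # exclusive

    times = counter.times
    raw = []
    for s, e in zip(starts, stops):
        onset = times[s]
        offset = times[e - 1] + 1.0 / counter.fs
        raw.append((onset, offset))

    merged: list[tuple[float, float]] = []
    for onset, offset in raw:
        if merged and onset - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], offset)
        else:
            merged.append((onset, offset))
    return DetectionEvents(tuple(merged), c_min=c_min, merge_gap_s=merge_gap_s)


def match_events(events: DetectionEvents, stim, tol_s: float = 0.5):
    """Greedy one-to-one matching of detection onsets to stimulus onsets.

    A stimulus at time ``t`` is hit if some unmatched event onset falls in
    ``[t, t + tol_s]``; each event matches at most one stimulus and vice
    versa, scanning both in time order.  Returns ``(hits, misses,
    false_alarms)``.

    ``stim`` may be a StimulusTrain-like object with an ``onsets`` attribute
    or a plain sequence of onset times.
    """

    if not tol_s > 0:
        raise ParameterError(f"tol_s must be positive, got {tol_s}")
    stim_onsets = np.asarray(getattr(stim, "onsets", stim), dtype=float)
    ev_onsets = events.onsets
    used = np.zeros(ev_onsets.size, dtype=bool)
    hits = 0
    for t in np.sort(stim_onsets):
        candidates = np.flatnonzero(~used & (ev_onsets >= t) & (ev_onsets <= t + tol_s))
        if candidates.size:
            used[candidates[0]] = True
            hits += 1
    misses = stim_onsets.size - hits
    false_alarms = int(np.count_nonzero(~used))
    return hits, misses, false_alarms
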