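"""Evaluation: PSD characterisation and stimulus cross-correlation.

Detection quality is scored as the maximum lagged Pearson correlation
between a detector's output and the stimulus trigger train rendered as a
binary waveform — the two are not synchronised (odour transport, response
latency, window latency), so the coefficient is maximised over integer
sample lags.  The four-variant harness compares {raw, EMA-filtered} x
{fixed threshold, D-Counter} pipelines on the same input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_core import EmaParams, ParameterError, SignalError, Trace, conditional_ema
from .detectors import (
    DCounterParams,
    FixedThresholdParams,
    d_counter_stream,
    extract_events,
    fixed_threshold,
)

__all__ = [
    "StimulusTrain",
    "EvalResult",
    "psd",
    "max_crosscorr",
    "compare_variants",
]


@dataclass(frozen=True)
class StimulusTrain:
    """Odour valve trigger train: onset times plus a common puff duration.

    Serves both as simulation ground truth and as the reference input for
    cross-correlation scoring; :meth:`to_binary` renders it as a rectangular
    0/1 waveform (1 while the valve is open) at any sampling rate.
    """

    onsets: np.ndarray
    duration: float

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=np.float64)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size < 1:
            raise ParameterError("a stimulus train needs at least one onset")
        if not self.duration > 0:
            raise ParameterError(f"puff duration must be positive, got {self.duration}")
        if onsets.size > 1:
            gaps = np.diff(onsets)
            if not np.all(gaps > 0):
                raise ParameterError("onsets must be strictly increasing")
            if not np.all(gaps > self.duration):
                raise ParameterError("inter-onset interval must exceed the puff duration")

    def __len__(self) -> int:
        return self.onsets.size

    def shifted(self, dt: float) -> "StimulusTrain":
        return StimulusTrain(self.onsets + dt, self.duration)

    def to_binary(self, fs: float, n_samples: int, t0: float = 0.0) -> Trace:
        """Rectangular 0/1 rendering at rate ``fs`` over ``n_samples``."""
        t = t0 + np.arange(n_samples) / fs
        out = np.zeros(n_samples)
        for onset in self.onsets:
            out[(t >= onset) & (t < onset + self.duration)] = 1.0
        return Trace(out, fs, t0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets, "duration_s": self.duration})


@dataclass(frozen=True)
class EvalResult:
    """Maximum lagged Pearson correlation and the lag achieving it."""

    max_xcorr: float
    best_lag_s: float

    def __post_init__(self):
        if not abs(self.max_xcorr) <= 1.0 + 1e-12:
            raise SignalError(f"correlation coefficient out of [-1, 1]: {self.max_xcorr}")


def psd(trace: Trace, segment_s: float = 1.0):
    """One-sided Welch power spectral density.

    Hann-windowed segments of ``segment_s`` seconds with 50% overlap, so the
    frequency resolution is 1/segment_s.  The density integrates to the
    signal variance (Parseval), which is how noise-floor and hum levels read
    off the plot correspond to mV^2.

    Returns ``(frequencies_hz, power_density)``.
    """

    nperseg = int(round(segment_s * trace.fs))
    if trace.samples.size < nperseg:
        raise SignalError(
            f"trace of {trace.duration:.3f}s is shorter than one {segment_s}s segment"
        )
    f, pxx = sps.welch(
        trace.samples,
        fs=trace.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return f, pxx


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r, or None when either segment is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return None
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def max_crosscorr(det_output: Trace, stim_trace: Trace, lag_max_s: float = 2.0) -> EvalResult:
    """Maximum Pearson correlation over integer sample lags within +/- lag_max_s.

    A positive ``best_lag_s`` means the detector output trails the stimulus
    (the usual case: odour transport plus response and window latency).
    Both inputs must share the sampling rate and be non-constant overall;
    lags whose overlapping segments are constant are skipped.
    """

    if det_output.fs != stim_trace.fs:
        raise ParameterError(
            f"sampling rates differ: {det_output.fs} vs {stim_trace.fs} Hz"
        )
    x = np.asarray(det_output.samples, dtype=float)
    y = np.asarray(stim_trace.samples, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise SignalError("cross-correlation of a constant signal is undefined")

    fs = det_output.fs
    lag_max = int(round(lag_max_s * fs))
    n = min(x.size, y.size)
    best_r, best_lag = -np.inf, 0
    for lag in range(-lag_max, lag_max + 1):
        if lag >= 0:  # detector delayed by `lag` samples relative to stimulus
            xa, ya = x[lag:lag + n], y[: n - lag]
        else:
            xa, ya = x[: n + lag], y[-lag:n]
        m = min(xa.size, ya.size)
        if m < 2:
            continue
        r = _pearson(xa[:m], ya[:m])
        if r is not None and r > best_r:
            best_r, best_lag = r, lag
    if not np.isfinite(best_r):
        raise SignalError("no lag produced a defined correlation")
    return EvalResult(max_xcorr=min(best_r, 1.0), best_lag_s=best_lag / fs)


def _detector_output(trace: Trace, method: str, s_win: float, th: float) -> Trace:
    """Run one detector and return its output as a Trace for correlation."""
    if method == "fixed":
        return fixed_threshold(trace, FixedThresholdParams(th))
    if method == "dcounter":
        ct = d_counter_stream(trace, DCounterParams(s_win=s_win, th=th, fs=trace.fs))
        return Trace(ct.counts.astype(float), trace.fs, trace.t0)
    raise ParameterError(f"unknown method {method!r}")


def compare_variants(
    trace: Trace,
    stim: StimulusTrain,
    alphas=(0.7,),
    s_wins=(0.2,),
    dc_th: float = -0.5,
    fixed_th: float = -0.5,
    lag_max_s: float = 2.0,
) -> pd.DataFrame:
    """Score the four pipeline variants {raw, EMA} x {fixed, D-Counter}.

    The D-Counter output enters the correlation as its raw integer counts,
    the fixed threshold as its binary train; Pearson normalisation makes
    the scale irrelevant.  Returns a tidy table with columns
    ``variant, alpha, s_win, th, max_xcorr, best_lag_s``.
    """

    rows = []

    def score(det: Trace, variant: str, alpha, s_win, th):
        stim_bin = stim.to_binary(det.fs, len(det), t0=det.t0)
        res = max_crosscorr(det, stim_bin, lag_max_s=lag_max_s)
        rows.append(
            dict(variant=variant, alpha=alpha, s_win=s_win, th=th,
                 max_xcorr=res.max_xcorr, best_lag_s=res.best_lag_s)
        )

    # raw pipelines
    score(_detector_output(trace, "fixed", None, fixed_th), "fixed", None, None, fixed_th)
    for s_win in s_wins:
        score(_detector_output(trace, "dcounter", s_win, dc_th), "dc", None, s_win, dc_th)
    # EMA pipelines
    for alpha in alphas:
        filt = conditional_ema(trace, EmaParams(alpha))
        score(_detector_output(filt, "fixed", None, fixed_th), "ema_fixed", alpha, None, fixed_th)
        for s_win in s_wins:
            score(_detector_output(filt, "dcounter", s_win, dc_th), "ema_dc", alpha, s_win, dc_th)
    return pd.DataFrame(rows)
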