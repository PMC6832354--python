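"""Synthetic EAG generator emulating the four recorded signal conditions.

Real EAG traces on a flying platform decompose into four superposed parts:
the pulsed negative odour response (< 10 Hz), slow baseline drift that
overlaps the response band (antenna drying, electrode effects), 50-70 Hz
power-line hum that survives analog notch filtering, and broadband
propeller/motor noise.  The generator builds each part from an independent
random substream of a single master seed, so toggling one component never
reshuffles another and the full trace is exactly the sum of its isolated
components.

The four conditions mirror the cross of propellers off/on x odour absent/
present.  Hum and drift are present in every condition (mains interference
and electrode drift do not care about the propellers); the condition
switches only the broadband propeller noise and the odour-response train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_core import ParameterError, Trace
from .evaluation import StimulusTrain

__all__ = [
    "CONDITIONS",
    "SimConfig",
    "make_stimulus_train",
    "response_kernel",
    "kernel_peak_time",
    "generate",
]

#: condition name -> (odour present, propeller noise present)
CONDITIONS = {
    "noise_off": (False, False),          # Type 1: propellers off, no odour
    "noise_off_odour": (True, False),     # Type 2: propellers off + odour puffs
    "noise_on": (False, True),            # Type 3: propellers on, no odour
    "noise_on_odour": (True, True),       # Type 4: propellers on + odour puffs
}
_ALIASES = {"type1": "noise_off", "type2": "noise_off_odour",
            "type3": "noise_on", "type4": "noise_on_odour"}


def make_stimulus_train(freq: float, n: int, duration: float = 0.2) -> StimulusTrain:
    """Periodic puff train: ``n`` onsets at ``k/freq``, each ``duration`` s.

    Matches the valve protocol used throughout: 200 ms puffs delivered at
    0.25, 0.5 or 1 Hz.  The puff must be shorter than the period.
    """

    if not freq > 0:
        raise ParameterError(f"stimulus frequency must be positive, got {freq}")
    if n < 1:
        raise ParameterError(f"need at least one stimulus, got {n}")
    if n > 1 and not duration < 1.0 / freq:
        raise ParameterError(
            f"puff duration {duration}s must be shorter than the period {1.0 / freq}s"
        )
    onsets = np.arange(n) / freq
    return StimulusTrain(onsets, duration)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the biexponential kernel's extremum (deepest point)."""
    return math.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)


def response_kernel(t, amplitude: float, tau_rise: float = 0.05, tau_decay: float = 0.3):
    """Biexponential odour-response kernel, zero for t < 0.

    ``A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` scaled so the minimum
    equals ``amplitude`` (a negative voltage, as EAG responses are negative
    deflections).  With the default time constants (50 ms rise, 300 ms
    decay) the kernel's spectral content is concentrated below 10 Hz,
    matching recorded odour responses.
    """

    if not (tau_decay > tau_rise > 0):
        raise ParameterError(
            f"need tau_decay > tau_rise > 0, got rise={tau_rise}, decay={tau_decay}"
        )
    if not amplitude < 0:
        raise ParameterError(f"response amplitude must be negative (mV), got {amplitude}")
    t = np.asarray(t, dtype=np.float64)
    shape = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    t_peak = kernel_peak_time(tau_rise, tau_decay)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return (amplitude / peak) * shape


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic EAG generator.

    Amplitudes are in mV, times in seconds.  The defaults represent a
    moderate-SNR recording: per-pulse response amplitudes jittered in
    [-1.5, -0.7] mV (well inside the observed [-1.8, 0.5] mV envelope, with
    visibly small and large responses), a bounded random-walk drift of the
    same order as typical detection thresholds, ~0.1 mV mains hum at 60 Hz
    and 0.2 mV broadband propeller noise at the acquisition rate.  The
    master ``seed`` fully determines the output.
    """

    condition: str = "noise_on_odour"
    fs: float = 1000.0
    duration_s: float | None = None
    # stimulus protocol
    stim_freq: float = 0.5
    stim_n: int = 10
    stim_duration: float = 0.2
    stim_start_s: float = 1.0
    # odour response
    amp_range: tuple = (-1.5, -0.7)
    tau_rise: float = 0.05
    tau_decay: float = 0.3
    response_latency_s: float = 0.2   # valve trigger -> odour arrival at antenna
    # baseline drift: bounded random walk plus optional slow sinusoid
    drift_step: float = 0.25      # mV per sqrt(s)
    drift_bound: float = 0.6      # soft reflecting bound, mV
    drift_sin_amp: float = 0.0
    drift_sin_freq: float = 0.1
    # power-line hum
    hum_amp: float = 0.1
    hum_freq: float = 60.0
    # broadband propeller/motor noise: a white electrical/acoustic floor plus
    # band-limited low-frequency vibration/buffeting that survives decimation
    broadband_sd: float = 0.2
    vibration_sd: float = 0.08
    vibration_cutoff: float = 20.0
    seed: int = 0

    def __post_init__(self):
        cond = _ALIASES.get(self.condition, self.condition)
        if cond not in CONDITIONS:
            raise ParameterError(
                f"unknown condition {self.condition!r}; choose from {sorted(CONDITIONS)} "
                f"or aliases {sorted(_ALIASES)}"
            )
        object.__setattr__(self, "condition", cond)
        if not self.fs > 2.0 * self.hum_freq:
            raise ParameterError(
                f"fs={self.fs} Hz cannot represent {self.hum_freq} Hz hum (need fs > 2*hum_freq)"
            )
        if not (np.isfinite(self.stim_freq) and self.stim_freq > 0):
            raise ParameterError(f"stim_freq must be positive, got {self.stim_freq}")
        if self.stim_n < 1:
            raise ParameterError(f"stim_n must be >= 1, got {self.stim_n}")
        if self.stim_n > 1 and not self.stim_duration < 1.0 / self.stim_freq:
            raise ParameterError(
                f"puff duration {self.stim_duration}s must be shorter than the "
                f"period {1.0 / self.stim_freq}s"
            )
        lo, hi = self.amp_range
        if not (lo <= hi < 0):
            raise ParameterError(f"amp_range must be negative with lo <= hi, got {self.amp_range}")
        for name in ("drift_step", "drift_bound", "drift_sin_amp", "hum_amp",
                     "broadband_sd", "vibration_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        if self.duration_s is not None and not self.duration_s > 0:
            raise ParameterError(f"duration_s must be positive, got {self.duration_s}")
        if not self.response_latency_s >= 0:
            raise ParameterError(
                f"response_latency_s must be >= 0, got {self.response_latency_s}"
            )

    @property
    def odour_on(self) -> bool:
        return CONDITIONS[self.condition][0]

    @property
    def propellers_on(self) -> bool:
        return CONDITIONS[self.condition][1]

    @property
    def effective_duration_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        span = (self.stim_n - 1) / self.stim_freq
        return self.stim_start_s + span + 3.0  # tail for the last response to decay

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amp_range"] = list(d["amp_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "amp_range" in d:
            d["amp_range"] = tuple(d["amp_range"])
        return cls(**d)


def _substreams(seed: int):
    """Fixed-order independent Generators, one per signal component."""
    names = ("response", "drift", "hum", "broadband", "vibration")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _response_component(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    train = make_stimulus_train(cfg.stim_freq, cfg.stim_n, cfg.stim_duration)
    lo, hi = cfg.amp_range
    amps = rng.uniform(lo, hi, size=cfg.stim_n)
    k_len = int(round(6.0 * cfg.tau_decay * cfg.fs))
    tk = np.arange(k_len) / cfg.fs
    for onset, amp in zip(train.onsets + cfg.stim_start_s + cfg.response_latency_s, amps):
        i0 = int(round(onset * cfg.fs))
        if i0 >= n:
            continue
        seg = response_kernel(tk, amp, cfg.tau_rise, cfg.tau_decay)[: n - i0]
        out[i0:i0 + seg.size] += seg
    return out


def _drift_component(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    # Random walk with hard reflection at +/- drift_bound; step scale is
    # drift_step per sqrt(second) so the wander rate is fs-independent.
    steps = rng.normal(0.0, cfg.drift_step / math.sqrt(cfg.fs), size=n)
    walk = np.empty(n)
    x = 0.0
    b = cfg.drift_bound
    for i in range(n):
        x += steps[i]
        if b > 0:
            if x > b:
                x = 2 * b - x
            elif x < -b:
                x = -2 * b - x
        else:
            x = 0.0
        walk[i] = x
    if cfg.drift_sin_amp > 0:
        t = np.arange(n) / cfg.fs
        phase = rng.uniform(0.0, 2.0 * math.pi)
        walk = walk + cfg.drift_sin_amp * np.sin(2 * math.pi * cfg.drift_sin_freq * t + phase)
    return walk


def _hum_component(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0.0, 2.0 * math.pi)
    t = np.arange(n) / cfg.fs
    return cfg.hum_amp * np.sin(2 * math.pi * cfg.hum_freq * t + phase)


def _broadband_component(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, cfg.broadband_sd, size=n)


def _vibration_component(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    # Propeller vibration/aerodynamic buffeting: white noise low-passed below
    # vibration_cutoff and rescaled to vibration_sd, so — unlike the white
    # floor — it survives anti-aliased decimation to the 100 Hz control rate.
    from scipy import signal as sps

    if cfg.vibration_sd == 0.0 or n < 20:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, size=n)
    sos = sps.butter(2, cfg.vibration_cutoff, btype="lowpass", fs=cfg.fs, output="sos")
    shaped = sps.sosfilt(sos, white)
    sd = shaped.std()
    if sd == 0.0:
        return np.zeros(n)
    return cfg.vibration_sd / sd * shaped


def generate(cfg: SimConfig, components: bool = False):
    """Generate one synthetic EAG trace plus its ground-truth stimulus train.

    The trace is the sum of the enabled components; an identical seed gives
    a bit-identical trace.  With ``components=True`` the per-component
    arrays are returned as a third element (dict), which is how the
    superposition property is exposed for testing and plotting.

    Returns ``(trace, stimulus_train)`` — the train is returned for every
    condition (it is the protocol that *would* have been delivered), but
    responses are only added when the condition includes odour.
    """

    n = int(round(cfg.effective_duration_s * cfg.fs))
    if n < 1:
        raise ParameterError("configuration yields an empty trace")
    rngs = _substreams(cfg.seed)

    parts = {
        "response": _response_component(cfg, n, rngs["response"]) if cfg.odour_on else np.zeros(n),
        "drift": _drift_component(cfg, n, rngs["drift"]),
        "hum": _hum_component(cfg, n, rngs["hum"]),
        "broadband": (_broadband_component(cfg, n, rngs["broadband"])
                      if cfg.propellers_on else np.zeros(n)),
        "vibration": (_vibration_component(cfg, n, rngs["vibration"])
                      if cfg.propellers_on else np.zeros(n)),
    }
    total = sum(parts.values())
    trace = Trace(total, cfg.fs)
    train = make_stimulus_train(cfg.stim_freq, cfg.stim_n, cfg.stim_duration).shifted(cfg.stim_start_s)
    if components:
        return trace, train, parts
    return trace, train
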