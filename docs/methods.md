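# Methods

## Signal model

A single-channel EAG voltage trace (mV) sampled uniformly at `fs` Hz is
modelled as the superposition of four parts:

1. **Odour response.** Each odour puff evokes a negative deflection modelled
   as a biexponential kernel
   `k(t) = A'·(exp(−t/τ_decay) − exp(−t/τ_rise))`, `t ≥ 0`,
   scaled so the kernel minimum equals a per-pulse amplitude drawn uniformly
   from a configurable range. Defaults: τ_rise = 50 ms, τ_decay = 300 ms,
   amplitudes in [−1.5, −0.7] mV. These constants are not measured values;
   they were chosen so the kernel satisfies the two observable constraints on
   real responses — single-response amplitude inside [−1.8, 0.5] mV and
   >90 % of spectral power below 10 Hz — while showing visibly variable
   response sizes. The kernel is placed `response_latency_s` (default
   0.2 s) after each valve trigger, representing odour transport from the
   valve to the antenna plus receptor latency; the ground-truth train keeps
   the trigger times, so detections naturally trail their triggers.
2. **Baseline drift.** A Gaussian random walk with step scale
   `drift_step/√fs` (default 0.25 mV/√s, i.e. the baseline typically wanders
   a quarter millivolt per second) reflected at ±`drift_bound` (default
   0.6 mV), optionally plus a slow sinusoid (0.05–0.5 Hz) for
   deterministic drift scenarios. The drift deliberately occupies the same
   sub-10 Hz band as the response — that overlap is the reason absolute
   thresholds and high-pass filters fail.
3. **Power-line hum.** A sinusoid at `hum_freq` ∈ [50, 70] Hz (default
   60 Hz, 0.1 mV) with a random phase. Hum is present in **all four**
   conditions: mains interference does not depend on the propellers.
4. **Propeller/motor noise** (only in the propellers-on conditions):
   a white Gaussian floor (`broadband_sd`, default 0.2 mV at the acquisition
   rate) plus a band-limited vibration/buffeting term — white noise
   low-passed at 20 Hz and rescaled to `vibration_sd` (default 0.08 mV).
   The split matters: the white floor is almost entirely removed by
   anti-aliased decimation to 100 Hz, while the vibration term survives in
   the detection band, which is what actually degrades detectors on a
   flying platform.

The four recording conditions are the cross of propellers off/on × odour
absent/present. Drift and hum are condition-independent; the condition
toggles only the response train and the propeller noise.

Each component draws from its own `numpy` substream spawned in fixed order
from the master seed, so (a) the same seed reproduces the trace bit for
bit, (b) toggling one component never reshuffles another, and (c) the full
trace is exactly the sum of the isolated components (tested).

### Calibration of the noise defaults

No numeric noise parameters exist for the real platform, so the defaults
were fixed once by jointly satisfying the qualitative behaviour of the
recorded conditions: (i) the EMA + D-Counter pipeline recovers all 10
puffs in ≥95 % of seeded runs; (ii) the D-Counter on the *raw* signal is
noticeably noisier and more variable across seeds, with low-coefficient
outliers; (iii) the fixed threshold is defeated by drift; (iv) odour-free
propellers-on traces almost never look like a large response (<1 % of
samples below −1.0 mV, Monte-Carlo over 20 seeds). The frozen values are
those listed above.

## Detection pipeline

Recordings are acquired at a high rate (1 kHz default in simulation;
10 kHz for typical hardware) and decimated to the 100 Hz control rate with
a polyphase FIR low-pass at 0.8× the target Nyquist; without this, the
50–70 Hz hum would alias into the response band. Naive every-q-th-sample
picking is available behind a flag for fidelity experiments. The detection
pipeline itself runs at 100 Hz with no further resampling.

**Conditional EMA.** `y[0] = x[0]`; falling steps (`x[n] − x[n−1] < 0`) are
smoothed with factor α, all other steps (including exact ties) with factor
1 − α. Ties take the rising branch because the branch test is strictly
negative. Every update is a convex combination, so the output can never
leave the input's range. α = 0.7 is the working default; 0.9 is the
heavier-smoothing alternative, and on the benchmark α = 0.7 is not
inferior (tested as non-inferiority of the median coefficient, not as a
magnitude).

**D-Counter.** For each window position (stride 1 sample) the count is the
number of samples strictly below the window's first sample; the deepest
drop Δmax is tracked from 0 and the count is zeroed unless Δmax ≤ th.
The count is attributed to the window's reference (first) index and is
causally available one window later — the algorithm's latency equals
`s_win`. `th` must be strictly negative: since Δmax starts at 0, any
non-negative `th` would zero every window, so it is rejected at parameter
validation. Making `th` more negative can only remove counts (the reset
fires on a superset of windows); the counter is invariant to adding a
constant to the trace but *not* to rescaling it when the deepest drop
straddles `th` — both properties are tested.

**Events.** Maximal runs of counts ≥ `c_min` become events; the default
`c_min = ceil(w/2)` (half the window dropping) rejects single-sample
noise. Runs closer than `merge_gap_s` are merged. The default merge gap is
0.1 s: its purpose is to bridge the 1–3-sample count flickers that occur
within a single response, and 0.1 s covers those comfortably while staying
well below the shortest inter-stimulus interval (1 s); a longer gap starts
gluing noise-triggered runs onto response runs, which corrupts onset
estimates. Event onsets are reported at the run's first reference index.

**Scoring.** Detections are matched greedily one-to-one to valve onsets:
a stimulus at `t` is hit if an unmatched event onset lies in
`[t, t + tol_s]`, `tol_s` = 0.5 s by default (odour transport latency +
response rise + window latency). Unmatched events are false alarms.
Detection quality over a whole trace is the maximum Pearson correlation
between the detector output (raw integer counts for the D-Counter, the 0/1
train for the fixed threshold — Pearson normalisation makes the scale
irrelevant) and the stimulus train rendered as a rectangular 0/1 waveform,
maximised over integer lags within ±2 s.

## Numerical choices and degenerate inputs

- Non-finite samples are rejected at `Trace` construction, never
  propagated.
- `Fraction(...).limit_denominator(10⁴)` turns an arbitrary rate ratio into
  a polyphase up/down pair; upsampling is refused.
- The high-pass reference is a causal 2nd-order Butterworth (forward-only,
  matching real-time use). It exists to demonstrate the negative result:
  removing drift by filtering also shrinks the response peak (tested).
- Welch PSD: Hann window, 1 s segments, 50 % overlap, constant detrend;
  the density integrates to the signal variance within 5 % (tested). For
  ~1/f² signals (drift), resolving sub-1 Hz concentration needs longer
  segments (10 s in the corresponding test).
- Cross-correlation of a globally constant signal is a defined error, not
  NaN; individual lags whose overlap is constant are skipped.
- The stimulus-train container enforces strictly increasing onsets and
  inter-onset intervals longer than the puff.

## Benchmark problem sizes

The seeded benchmark uses 20 seeds × 3 puff rates (0.25/0.5/1 Hz) × 2
window sizes (0.1/0.2 s) with 10 puffs per run (traces of 13–40 s at
1 kHz); the variant-comparison table uses 24 seeds with rates cycled
across seeds. These sizes give stable medians and quartiles while keeping
the full suite fast enough to run routinely.

## Limitations

- The response kernel, time constants, latency and all noise amplitudes
  are plausible emulations constrained by qualitative observations, not
  fits to recordings; passing the benchmark shows the pipeline behaves as
  designed under these conditions, not that it matches any particular
  animal's coefficients.
- The generator does not model plume physics, antenna death/response decay
  over a session, electrode artefacts, or concentration coding; responses
  are amplitude-jittered but otherwise stereotyped.
- Per-preparation coefficient values from real recordings depend on the
  individual antenna and are outside what simulation can reproduce; only
  orderings and dispersion comparisons are asserted.
- The D-Counter reports onset/offset timing, not concentration; it is the
  right tool for onset-triggered search behaviour, not gradient following.
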