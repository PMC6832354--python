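# eagdc — odour-response detection for noisy electroantennograms

An electroantennogram (EAG) records the summed receptor potential of an
insect antenna; an odour puff produces a transient **negative** deflection of
roughly −1.8 to 0.5 mV whose spectral content sits below 10 Hz. On a flying
platform the recording is contaminated by slow baseline drift (antenna
drying, electrode effects) that occupies the *same* band as the response,
50–70 Hz power-line hum, and broadband propeller/motor noise. An absolute
voltage threshold is defeated by the drift, and a high-pass filter that
removes the drift also attenuates the response itself.

`eagdc` implements the two-stage detection scheme built for this regime,
plus everything needed to evaluate it without recorded data:

- **Conditional EMA filter.** A direction-dependent exponential moving
  average with smoothing factor α ∈ (0, 1):

  ```
  y[0] = x[0]
  y[n] = α·x[n] + (1−α)·y[n−1]        if x[n] − x[n−1] < 0   (falling)
  y[n] = (1−α)·x[n] + α·y[n−1]        otherwise              (rising)
  ```

  With α > 0.5 falling (odour-evoked) excursions are tracked almost
  unsmoothed while rises are heavily damped, enhancing the negative
  response relative to recovery and positive noise.

- **D-Counter (dropping counter).** Slide a window of `w = round(s_win·fs)`
  samples; take the first sample as the reference; count the samples with
  `sig[i] − sig[0] < 0`, tracking the deepest such drop Δmax (initialised
  at 0); if `Δmax > th` (a **relative** depth threshold, negative mV) reset
  the count to 0. Counting differences makes the detector immune to
  baseline drift.

- **Fixed threshold** baseline (`1` wherever `sig[n] < th_abs`), anti-aliased
  decimation (10 kHz/1 kHz → 100 Hz), Welch PSD characterisation, and the
  detection-quality metric: the **maximum lagged Pearson correlation**
  between a detector's output and the stimulus trigger train.

- **Synthetic EAG generator** covering the four recording conditions
  (propellers off/on × odour absent/present): biexponential response
  kernels with per-pulse amplitude jitter, bounded random-walk drift,
  mains hum, and propeller noise (white floor + band-limited vibration),
  each from an independent substream of one master seed.

## Worked example

Simulate a noisy recording (condition: propellers on + odour; 10 puffs of
200 ms at 0.5 Hz), then detect with the EMA + D-Counter pipeline at 100 Hz:

```
$ eagdc simulate --condition type4 --freq 0.5 --n 10 --seed 1 --out-prefix ex
INFO wrote ex_trace.csv (22000 samples at 1000 Hz), ex_stim.csv, ex_config.yaml

$ eagdc detect --input ex_trace.csv --decimate-to 100 --alpha 0.7 \
        --s-win 0.2 --th -0.5 --out-prefix ex
INFO wrote ex_events.csv (10 events)

$ head -4 ex_events.csv
onset_s,offset_s
1.03,1.25
3.05,3.2399999999999998
5.11,5.25
```

All 10 puffs are recovered; each event onset trails its valve trigger (at
1 s, 3 s, 5 s, …) by the odour transport latency plus the window latency.
The multi-seed benchmark compares the four pipeline variants
({raw, EMA} × {fixed threshold, D-Counter}) by their maximum
cross-correlation with the stimulus train:

```
$ eagdc bench --seeds 5 --out bench.csv
{
  "median_max_xcorr": {
    "dc": 0.8827475157404013,
    "ema_dc": 0.9205036317616584,
    "ema_fixed": 0.3882948319958224,
    "fixed": 0.40964388045094974
  }
}
```

The drifting baseline caps the fixed threshold near 0.41 while the
relative-depth D-Counter reaches 0.88–0.92; EMA filtering additionally
narrows the D-Counter's spread across preparations (see
`tests/test_acceptance.py`).

The same operations are available as a library:

```python
from eagdc import simulate_benchmark_trace, ema_dcounter_events, match_events

trace, train = simulate_benchmark_trace(seed=1, stim_freq=0.5)
events = ema_dcounter_events(trace, alpha=0.7, s_win=0.2, th=-0.5)
hits, misses, false_alarms = match_events(events, train, tol_s=0.5)   # (10, 0, 0)
```

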