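# plsp — phase-locked stimulus presentation toolkit

Cortical excitability waxes and wanes within each cycle of the occipital
α rhythm (8–12 Hz), so *when* in the cycle a stimulus arrives may decide
whether it is seen. Testing that idea causally requires presenting
stimuli locked to chosen phases of the *ongoing* oscillation — which
means forecasting the instantaneous phase in real time, from data that
end at the present moment, and firing the stimulus early enough to
absorb the lag between the trigger decision and the stimulus landing.

`plsp` is a toolkit for building and validating such closed-loop
experiments in simulation. It provides:

- **Three causal forecasters** of instantaneous phase Φ and frequency
  IF at the current sample `t_current` of a band-pass filtered window:
  - **AR** — Yule–Walker autoregressive fit (BIC order selection) with
    iterative forward prediction past the window end, then
    Hilbert-transform phase readout away from the edge;
  - **FFT** — zero-padded spectrum, dominant-component phase projected
    forward at the dominant frequency;
  - **AKF** — an adaptive Kalman filter on the state `x = [Φ, IF]` with
    constant-frequency transition `F = [[1, Δt], [0, 1]]`, covariance
    inflation `P̂ = α²FPFᵀ + Q`, wrapped innovation, Joseph-form update
    `P = (I−KH)P̂(I−KH)ᵀ + KRKᵀ`, and an adaptive α that drops from 1
    to 0.8 whenever the measured IF leaves the band (down-weighting
    noise- or edge-corrupted measurements).
- **The closed-loop simulator**: data consumed in 30-sample chunks, a
  trailing ~3-cycle (300 ms) analysis window, zero-phase FIR band-pass,
  forecaster, and the scheduling rule
  `t_delay = fs · (Φ_desired − Φ_current) / (360 · IF_current)`:
  when the wrapped forward distance to the desired phase first falls
  inside the phase-delay margin and the delay covers the system lag, a
  trigger is scheduled to land exactly on the desired phase; otherwise
  the pipeline re-initiates on the next chunk.
- **Circular performance scoring** — accuracy (circular mean of
  absolute phase distances between achieved and desired phases) and
  precision (their circular SD).
- **Offline statistics** for validating phase-locked experiments:
  cosine-similarity intertrial phase coherence
  `ITC_CS = 2/(N(N−1)) Σ_{i<j} cos(θ_i − θ_j)` (unbiased in trial
  count), cut-and-swap surrogate nulls, jackknife fractional-peak
  onset/offset latencies, FFT-initialized sinusoid fitting, and a
  one-up/one-down staircase with a simulated psychophysical observer.
- **A synthetic-signal generator** with analytic ground-truth phase
  (fixed or drifting tone, exact-SNR white noise), so every estimator
  can be scored against truth.

## Worked example

`examples/01_closed_loop_simulation.py` generates a 60-s tone at
10.047 Hz with white noise at linear SNR 1 and runs the adaptive-Kalman
closed loop, targeting the four cardinal phases:

```
tone frequency: 10.047 Hz
56 triggers scheduled
  desired     0 deg: n=14  accuracy= 20.6 deg  precision= 23.4 deg
  desired    90 deg: n=14  accuracy= 31.0 deg  precision= 30.6 deg
  desired   180 deg: n=14  accuracy= 42.7 deg  precision= 31.7 deg
  desired   270 deg: n=14  accuracy= 23.6 deg  precision= 21.7 deg
pooled: accuracy=29.2 deg, precision=28.3 deg over 56 triggers
```

Accuracy is the circular mean of the absolute distances between the
phase actually achieved at each trigger (read from the analytic ground
truth) and the desired phase; 0° would be perfect locking and 90° is
what uniformly random timing would give. At SNR 1 — noise energy equal
to signal energy — the loop concentrates stimuli around the requested
phases of an oscillation it only ever sees causally.

The other examples cover the forecaster comparison grid
(`02_compare_forecasters.py`), coherence against surrogate nulls
(`03_itc_and_surrogates.py`), latency estimation and sinusoid fitting
(`04_latency_and_sinusoid_fit.py`) and staircase calibration
(`05_staircase_calibration.py`). A thin CLI wraps the loop:
`plsp simulate`, `plsp run`, `plsp evaluate`, `plsp compare`.

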