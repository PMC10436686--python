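# Methods

This note documents the models implemented in `plsp`, the parameter
choices that matter, what the synthetic benchmark does and does not
show, and the numerical decisions taken where the design was open.

## Conventions

All phases are degrees in the half-open interval [−180, 180), cosine
convention: phase 0 at the positive peak of the oscillation, advancing
with time (a 10 Hz rhythm advances 3.6°/ms). 180 wraps to −180 so the
boundary is deterministic. Instantaneous frequency (IF) is the scaled
derivative of the unwrapped analytic phase, in Hz; inside the Kalman
filter the velocity state is kept in deg/ms (12 Hz ≙ 4.32 deg/ms) and
converted at the interface.

Circular accuracy is the circular mean of *absolute* phase distances
(range [0, 180]); precision is the circular SD of those distances,
`sqrt(2(1−R̄))` in radians (the angular deviation; `sqrt(−2 ln R̄)` is
also exposed). Both are rotation-invariant.

## Synthetic signals

The generator produces single-tone cosines with the frequency either
fixed or drawn uniformly from a band (default 8–12 Hz), 1000 Hz
sampling, with the exact phase track retained. One tone per
realization keeps the ground truth analytic; a drifting variant
(reflected Gaussian random walk of the frequency inside the band,
default step SD 0.02 Hz/sample) probes non-stationarity. White
Gaussian noise is rescaled so the summed-square signal-to-noise ratio
is *exactly* the requested linear value; the benchmark operating point
is SNR 1 (0 dB), the regime where real electrophysiological recordings
tend to live or below.

What the generator does **not** emulate: 1/f background spectra,
amplitude modulation of the rhythm, multi-component α with several
simultaneous spectral lines, artifacts, and sensor mixing. Passing the
benchmark therefore shows that an estimator tracks a noisy narrowband
oscillation causally — not that it survives every property of real
MEG/EEG.

## The closed-loop pipeline

Chunks of 30 samples arrive sequentially (the delivery granularity of
real-time acquisition); once at least 300 ms of data exist, the
trailing 300-ms window (≈3 α cycles) is zero-phase band-pass filtered
and handed to the chosen forecaster, which returns Φ and IF at the
window's last sample. The wrapped forward distance ΔΦ to the current
desired phase is computed; if ΔΦ ≤ margin (the *phase-delay margin*,
45°/90°/180° being typical choices) the trigger is scheduled
`round(fs·ΔΦ/(360·IF))` samples ahead, landing on the desired phase.
If the required delay is shorter than the configured system lag the
lag cannot be compensated and the pipeline re-initiates on the next
chunk. After each trigger a refractory period (default 1 s) emulates
inter-trial structure. Desired phases are either blocked (contiguous
equal-duration blocks, default — matching blocked experimental runs)
or interleaved trigger-by-trigger. The simulator is sample-locked and
fully deterministic given trace and configuration.

`system_lag_ms` defaults to 0. A realistic stimulation chain has
~50 ms of lag, but at α frequencies 50 ms equals half a cycle: it can
only be compensated when the decision is taken a half cycle or more
ahead (margins ≥ 180°). Simulations probing the margin effect at 45°
are only possible with the lag disabled, so the default keeps the two
knobs independent; tests exercise the lag path with margins that admit
it.

### Filtering

"Zero-phase band-pass" is a forward–backward linear-phase FIR (Hamming
window design), so the net phase response is identically zero; a
single-pass variant with group-delay compensation exists for
strict-causality experiments. Two different orders are used, and the
distinction matters:

- **Offline, full records**: order = three cycles of the low cutoff
  (`3·fs/low`, 374 at 1000 Hz for an 8 Hz low edge) — a true band-pass
  (DC gain ~3·10⁻³, strong stop-band rejection), automatically reduced
  when a segment cannot support two passes.
- **Real-time windows** (inside the loop): order = 3 × low cutoff in
  taps (24 for the α band). In a 300-sample window a long filter's
  forward–backward transient biases the analytic phase near the window
  end — the one sample the forecaster must read — by ~10°, which is
  worse than the weak filter's incomplete noise rejection. The weak
  filter leaves the window tail unbiased (< 2°) and pushes the noise
  burden onto the estimators, which is exactly the regime the AKF's
  measurement-noise setting describes (below). Both orders are
  configurable (`BandSpec.order`, `PLSPConfig.fir_order`).

## The forecasters

**AR.** 75 ms is trimmed from both window ends (filter/Hilbert edge
zones); the 150-sample core is fitted by Yule–Walker. The
autocovariance is biased and *not* demeaned (the `aryule` convention —
demeaning a non-integer number of cycles grossly distorts short-window
fits). One Levinson–Durbin recursion yields coefficients for all
candidate orders 2–30; the order minimizing the BIC of empirical
one-step residuals (evaluated on a common sample span) wins. BIC from
the theoretical Yule–Walker innovation variance instead collapses to
order 2 on near-deterministic signals and is not used. The model is
iterated forward to 75 ms past `t_current`, and the analytic phase of
the (core + prediction) segment is read at `t_current`, now far from
any edge. Known limitation: on a 1.5-cycle core the biased
autocovariance carries a leakage term of order `1/(n·sin ω)` (~10%)
whose effect depends on the phase of the tone at the window start;
even the best candidate order can be tens of degrees off at
unfavorable offsets, noise or no noise. This is intrinsic to
Yule–Walker at this window length and is the main reason AR trails the
other estimators throughout.

**FFT.** The window is zero-padded to 1800 points (0.556 Hz bin
spacing); the maximum-power bin is the dominant component (ties, within
1e-9 relative power, break toward the lower frequency); the phase at
`t_current` is the bin phase (referenced to the first window sample)
advanced by `360·f_dom·(N−1)/fs`, and IF = f_dom. On a single tone
this is close to a matched filter: phase errors of a few degrees at
SNR 1, limited by bin quantization and leakage. Its weakness is
structural, not stochastic: everything is reduced to one stationary
sinusoid, so multi-component or drifting signals violate the model.

**AKF.** State `x = [Φ (unwrapped), IF]`, transition
`F = [[1, Δt], [0, 1]]` (no acceleration: frequency locally constant
within the window), process noise Q = 0. The filter re-initializes for
every window half a nominal cycle (50 ms at the 10 Hz band center)
before `t_current`, from the measured analytic phase and one-sample
IF, with `P₀ = diag(R₀, ẋ_max²)`; it then alternates predict
(`P̂ = α²FPFᵀ + Q`) and update per sample. The measurement is the
window's analytic phase; the innovation is wrapped to [−180, 180)
before the linear update (the wrapped-Gaussian/von-Mises
approximation), and the covariance update uses the Joseph form, which
preserves symmetry and positive semidefiniteness by construction.
Parameters: `R = R₀ = 93² deg²` — the phase-measurement error variance
of band-passed data at SNR 1 — and `ẋ_max = 4.32 deg/ms`, the 12 Hz
band edge. α is nominally 1 and becomes 0.8 whenever the measured
one-sample IF leaves the band, deflating the predicted covariance and
hence the Kalman gain: suspect measurements (noise spikes, edge
distortion, phase slips) are partially ignored in favor of the
prediction. Negative or non-finite IF estimates are clamped to
10⁻³ Hz and flagged; the loop refuses flagged estimates and waits for
the next chunk.

### What the benchmark shows about the estimators

On the stationary single-tone benchmark at SNR 1 (60-s traces, margin
180°, pooled over the four desired phases) the measured pooled
accuracies are: FFT ≈ 5–15°, AKF ≈ 20–39°, AR ≈ 43–66°. The AKF beats
AR in every seed; the common expectation that the AKF also beats
FFT does **not** hold here, because a correctly-referenced
dominant-component fit is near-optimal for exactly this signal class —
a stationary tone in white noise — while the AKF uses only the last
half cycle of data and its frequency posterior (SD ≈ 2.5 Hz under
R = 93²) feeds directly into the scheduled delay. Closed-loop studies
that report the opposite ordering do so on signals that are
non-stationary and multi-component, where the FFT's single-sinusoid
reduction is the wrong model; on this toolkit's drifting-tone and
multi-component variants the gap indeed narrows to parity, but FFT is
not decisively beaten under any variant tried. The noiseless sanity
bounds behave accordingly: FFT ≈ 0°, AKF ≈ 1.2° (< 3°), while AR's
Yule–Walker pathology leaves it near 40° even without noise. These
results are reported as measured; no parameter was adjusted to reorder
them.

A shorter phase-delay margin (45° vs 180°) improves accuracy for AKF
and AR in 10/10 seeds (less forward projection, fresher estimates);
for FFT, whose error is dominated by a margin-independent window-level
bias, the paired improvement appears in only ~7/10 seeds.

## Offline statistics

**ITC_CS.** The mean cosine of all pairwise phase differences across N
trials, computed through the identity
`(|Σe^{iθ}|² − N)/(N(N−1))` (O(N) instead of O(N²); equal to the
pairwise sum to 1e−12, property-tested). Range [−1, 1]; 1 for
identical phases, ~0 for uniform spread; unbiased in N, unlike the
resultant-length coherence.

**Cut-and-swap surrogates.** Each repetition cuts every raw trial at
an independent uniform random point and swaps the two sections — a
circular rotation that preserves the within-trial sample distribution
and phase dynamics while destroying alignment to the event. Phases are
re-extracted from the rotated *raw* data through the same
filter–Hilbert path and ITC_CS recomputed per time point; the chance
level is the mean over repetitions (default 1000).

**Jackknife latency.** Onset (offset) latency is the first (last)
crossing of 30% of the rectified peak within a search window, with
linear interpolation between samples; one estimate per leave-one-out
grand average, and the mean of those is reported. Identical inputs
reproduce the single-waveform crossing exactly; a subsample that never
crosses raises an error naming it.

**Sinusoid fitting.** `y(t) = a·sin(2πft + Φ) + b`, offset initialized
at the sample mean, (a, f, Φ) at the dominant Fourier component, then
nonlinear least squares. Amplitude is normalized non-negative (sign
absorbed into Φ, reported in the sine convention;
`sine_phase_to_cosine` converts). Constant input returns a = 0 with
r² defined as 0.

**Staircase.** One-up/one-down fixed-step staircase against an
observer whose detection probability is logistic in stimulus level
(P = 0.5 at threshold). The rule equilibrates where detection is 50%;
`converged_level` is the mean of reversal levels. Calibration runs
terminate after five reversals (defaults: step 0.05, start
threshold + 6 steps in normalized luminance units). For the long-run
equilibrium estimate the acceptance script averages reversal levels
after a 10-reversal burn-in: with ~1100 reversals in 2000 trials this
estimator has ~1 percentage-point spread, versus ~7 for the mean of
the last 20 reversals alone.

## Problem sizes and determinism

The test suite's closed-loop comparisons use ten 60-s traces per
condition (≈2000 chunk decisions each; ~25 s total on one core), which
gives 50–60 triggers per run — enough for pooled circular statistics
with ±3–4° seed-to-seed spread. Surrogate tests use a few hundred
repetitions on ~15×800-sample trial sets. Every stochastic component
takes an explicit integer seed (numpy `default_rng`); identical seeds
give bit-identical traces, event logs and surrogate distributions.
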