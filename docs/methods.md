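# Methods

## Scope and model

`floatcall` implements the on-board signal-processing chain and the static
resource models of an autonomous hydrophone float (a profiling float that
drifts at depth, listens, and reports detections by satellite). Three things
are modelled:

1. **A rule-based blue-whale D-call detector.** A D-call is a narrow-band
   vocalization sweeping downward, typically from 80 to 20 Hz. The detector
   operates on 64-sample short-time spectra with 50% overlap (at the 200 Hz
   working rate this is a 0.32 s frame every 0.16 s), keeping the 32 bins
   below Nyquist. Bins under 20 Hz are zeroed — they carry flow and
   micro-seismic noise. Per frame it computes the peak-ratio statistic
   (max1+max2)/(max5+max6) over bin magnitudes, which is large only when a
   single narrow band dominates, and the frequency of the
   maximum-amplitude bin. An STA/LTA (short-term average over long-term
   average, 5 and 15 frames) smooths the ratio series; frames where the
   smoothed value is at or above the trigger threshold form candidate
   windows. Each window's peak-frequency trajectory is truncated to the
   span from its maximum to the first following local minimum (edge frames
   of a window are unreliable); downward / upward / stable bin transitions
   are counted; and seven empirical checks decide acceptance (window length
   > 4 frames, mean ratio > 2.5, n_down > 3·n_up, n_down > 2,
   n_down > 0.25·n_stable, max frequency > 40 Hz, no frequency change over
   20 Hz within any 0.8 s span). The onset reported is the trigger-frame
   time.

2. **A simplified seismic P-wave trigger**: a causal 4th-order Butterworth
   high-pass at 1 Hz followed by a sample-wise STA/LTA (10 s over 100 s) of
   the absolute amplitude; trigger times are the first samples of maximal
   supra-threshold runs. The discrimination stage that a full seismic chain
   would add (wavelet-band distances to reference distributions) is out of
   scope.

3. **Static resource models** evaluated from an application description
   alone: processor utilization U = Σ C_i/T_i against the Liu–Layland
   rate-monotonic bound n(2^{1/n}−1) (sufficient, not necessary); dive
   duration with a Poisson model of ascent requests; per-stage energy
   E_stage = E_act + E_sens + E_board + E_com; expected satellite bytes
   from probability-annotated recording calls; and lifetime
   LT = (E_bat/E_dive)·T_dive. Composition of two applications onto one
   float requires equal dive depth and maximum duration, consistent
   configuration of any shared sensor, and combined schedulability.

## Key numerical and design choices

- **STA/LTA windows both end at the current sample** (the long window
  contains the short one), and warm-up uses the available prefix for both
  averages so no frames are dropped. Consequence: the statistic is bounded
  by `lta_len/sta_len` (3 for the 5/15 defaults) and hovers near 1 on
  stationary input. A zero long-term mean yields 0 (signal absent).
- **D-call trigger threshold 1.5 (default).** The detector's coefficients
  are meant to be settled by simulation before deployment. On synthetic
  scenes the smoothed ratio stays near 1 (fluctuations ≲ 1.4) on noise and
  peaks near 1.8–2.5 during a sweep, so thresholds in 1.2–1.6 give
  identical benchmark results; 1.5 is the middle of that plateau. Trigger
  comparison is ≥, detrigger <; a window still open at end-of-signal closes
  there. A configurable pre-trigger buffer (default 0) can prepend frames,
  since the trigger slightly lags the call onset.
- **Peak ratio degeneracies**: an all-zero masked spectrum gives ratio 1
  (no contrast); a zero denominator with nonzero numerator returns a
  configurable cap (default 1000). The six maxima are plain order
  statistics; an optional minimum bin separation is available but off by
  default.
- **Trajectory truncation** keeps the sub-list from the (earliest) maximum
  to the first index after it where the value turns upward; monotone
  trajectories keep everything. Transition counting operates on bin
  indices (the trajectory is quantized to 32 bins); checks 6–7 convert to
  Hz. The mean-ratio check uses the truncated span, consistent with the
  truncation's purpose of dropping spurious edge values. Check 7 is read
  as: over every pair of retained points separated by at most 0.8 s
  (converted to frames via the hop), |Δf| ≤ 20 Hz — the only reading
  well-defined for arbitrary sample rates.
- **Window function**: rectangular by default (the minimal embedded
  implementation), Hann by flag. Spectra are linear magnitude; the ratio
  is scale-invariant either way.
- **Seismic trigger threshold has no default** — it is bounded by
  lta_s/sta_s = 10 and must be chosen per deployment; tests use 3.
- **Ascent pump energy** uses the quadratic form coeff·depth² plus a
  constant surface bladder-fill term; parking actuation is free; descent
  is a small configured constant.
- **Mean parking duration** (1/r)(1−e^{−rD}) is exactly E[min(T, D)] for
  exponential inter-request times T censored at the default duration D, so
  no separate "exact" variant exists.
- **Activation merging** is computed exactly over the hyperperiod with
  rational arithmetic, schedules phase-aligned at t=0 starting active.
  Months are 30 days for monthly-volume normalization.
- **Hardware constants are never defaulted**: board/sensor/modem powers,
  transmission speed, float speeds and pump coefficient vary per
  instrument, so any model needing a missing constant raises an error
  naming it. The tests carry a documented example profile.

## Synthetic data: what it emulates and what it does not

The generator produces Gaussian background noise at a requested RMS,
D-calls as constant-amplitude power-law frequency sweeps (linear by
default, curvature exposed) with a raised-cosine 10% taper, and
seismic-like transients as tapered noise bursts. Scenes are sums of event
waveforms over noise, with exact ground-truth onsets. Defaults: 200 Hz
sample rate, 4 s call duration (a seconds-scale choice; no canonical value
exists), 80→20 Hz sweep.

The benchmark scene used by the acceptance tests places 20 D-calls at
uniform-random, ≥ 20 s-separated onsets in 30 minutes of noise, call
amplitude 0.5 over noise RMS 0.05 (a 20 dB amplitude ratio — a clearly
audible call). This emulates the *shape* statistics the detector keys on,
not real ocean soundscapes: no shipping-noise spectra, propagation loss,
multipath, call-to-call variability in sweep rate and bandwidth, or
overlapping choruses. Perfect precision/recall on these scenes therefore
demonstrates correctness of the processing chain at favourable SNR, not
field performance: on real annotated datasets rule-based detectors of this
family show high precision with recall nearer one half.

WAV I/O is 16-bit PCM mono with clipping to [-1, 1]; round-trips preserve
length exactly and amplitude to one quantization step.

## Problem sizes

Tests and the acceptance script run on 30-minute scenes at 200 Hz
(~360 k samples, ~11 k frames) for the D-call benchmark and 10-minute
scenes at 40 Hz for the seismic trigger; the resource models are
closed-form. The full suite completes in a few seconds on one core.

## Known limitations

- The schedulability check uses the Liu–Layland bound only; a task set
  above the bound may still be feasible (the property tests assert the
  sufficient direction against an exhaustive rate-monotonic simulation).
- Worst-case execution time of a mode is the sum of all its call times —
  branch structure is not modelled beyond per-call probabilities, which is
  conservative for timing and exact in expectation for bytes.
- The event matcher's greedy nearest-first policy can in principle fall
  below optimal bipartite matching when collars overlap several candidates;
  the optimal policy is available via a flag and the property tests bound
  the gap.
- The seismic path stops at the trigger; no discrimination, magnitude or
  ascent-request logic.
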