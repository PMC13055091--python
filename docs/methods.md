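# Methods

This note documents the models, defaults and numerical choices behind
`knotbp`, and what the bundled synthetic studies do and do not show.

## Synthetic sessions and their ground truth

A session is rendered from a protocol of constant-condition segments
(label, duration, SBP/DBP, HR). Beat (R-wave) times advance by RR =
60/HR per segment, optionally with seeded uniform RR jitter; the first
beat starts 0.5 s into the session and a 1 s margin keeps whole cycles
inside the grid. Per beat:

* the pressure-channel transit time is the inverse of the linear
  calibration, `PTT_ET = (SBP − b)/a` in ms — so the session's BP↔PTT
  relation is known exactly;
* the PPG transit time adds a constant site delay (default **50 ms**,
  a synthetic stand-in for the longer heart→fingertip path, not a
  physiological claim);
* pulse feet land at `S-wave time + PEP + PTT`, with the pre-ejection
  period constant per subject (default **30 ms**, configurable — its
  true value varies and is not identifiable from these signals).

The returned ground truth contains every rendered event time, per-beat
transit times, and the per-segment BP/HR — the basis for closure tests.

**ECG.** Sum-of-Gaussians beat morphology (P, Q, R, S, T), with the S
deflection deep and narrow so it is both the per-beat global minimum and
a sharp fiducial. The default amplitudes give the beat a net *negative*
area: after the 4 Hz → 1 Hz over-filter the beat collapses into one
dominant trough, which is what the S-foot detector needs. A
`tachycardia` flag adds a second bump on the T wave (the extra T-wave
peak seen around 118 bpm). Rendering refuses kernels narrower than one
sample (aliasing guard).

**Pulse cycles.** Gamma-like rise (`(τ/τ_p)^k e^{k(1−τ/τ_p)}`) plus an
additive Gaussian dicrotic bump, normalized to [0, 1] per cycle so each
cycle spans exactly [Pd, Ps]. Systolic timing is specified in absolute
seconds (time-to-peak 0.12 s, dicrotic wave at 0.34 s, raised-cosine
fade at 0.40–0.50 s) and the whole systolic program stretches or
compresses (scale clamped to [0.5, 1.5]) so that the **last 0.40 s of
every cycle is exactly at the diastolic baseline** regardless of heart
rate. This quiescent end-diastole is deliberate: it makes the cycle
foot a well-defined onset and gives the causal conditioning chains a
heart-rate-independent settling window (see *Detection latency* below).
The pressure channel renders SBP/DBP divided by 100 (pressure-
proportional sensor units); the PPG rides on a DC perfusion baseline
(1.0) with 0.4 pulsatile amplitude, giving both pulse chains the same
relative modulation.

**Noise.** Additive white Gaussian noise, sinusoidal baseline wander
(default 0.25 Hz) and powerline interference (default 60 Hz), each with
seeded phases, applied independently per channel in channel units.
Defaults (white SD 0.01, wander 0.05, powerline 0.005) emulate a clean
wearable recording. What the generator does **not** emulate: motion
artifacts, waveform-shape changes with BP or posture, arterial-path
dispersion, sensor drift, PEP variability, or any PPG optics — so
passing tests demonstrate pipeline correctness under the stated model,
not robustness on real recordings.

## Conditioning

All filters are first-order RC-discretized single poles,
`y[n] = αx[n] + (1−α)y[n−1]` with `α = 1 − e^(−2πf_c/f_s)`, unit DC
gain. The pressure chain is square → digital gain (default 1.0, the
hardware's amplification factor being unspecified) → 6 Hz → 3 Hz; the
order square-then-filter is a documented choice. The ECG "roughening"
chain is 4 Hz → 1 Hz. Default mode is **causal** (the real-time
firmware behavior). Zero-phase mode, intended for offline analysis, is
realized spectrally: the forward-backward pass of a single pole has the
zero-phase magnitude-squared response |H|², and applying that response
on the DFT (circular boundary) keeps the operator diagonal in
frequency, so zero-phase cascades commute exactly — an edge-padded
forward-backward recursion would only approximate this near the signal
ends. Group-delay differences between the ECG and pulse chains are not
corrected: they are constant per chain and absorbed by the calibration
intercept, exactly as in the hardware.

## Peak detection

The rolling z-score detector codes sample i as ±1 when it deviates from
the mean of the previous `lag` samples of an influence-damped history by
more than `threshold` standard deviations of that history; flagged
samples enter the history with weight `influence` only. Defaults:
lag 0.25 s, threshold 3.5, influence 0.1, refractory 0.25 s. These are
not hardware-specified values; they were chosen, together with the
generator defaults above, so that noiseless synthetic sessions yield
exactly one event per beat per channel across the supported heart-rate
range, and they are all overridable via `RunConfig`. A σ floor of
1e-9 × signal range prevents zero-variance divisions on flat history
(a constant signal codes all zeros rather than raising). Event time is
the **onset** of a flagged run (first-time-pulse semantics), with runs
closer than the refractory period merged to the earliest.

**Detection latency.** On a causal chain, a threshold-crossing onset
necessarily lags the physical foot. Because every cycle ends in the
same 0.40 s quiescent tail, the detector's rolling window sees the same
decay transient at every foot, so this latency is a *constant* (+8–9
samples at 400 Hz) — the same for the ECG, PPG and pressure chains by
construction of the default morphology and template. Constant chain
latencies cancel in PTT differences and otherwise fold into the
calibration intercept. Two beat classes are excluded from closure
checks: the first beat of a session (filters still settling from zero
state) and the first beat after a stepwise BP change (the protocol's
idealized discontinuity lands inside the rolling window); both measure
the protocol's artifice, not the pipeline.

## Beat matching and PTT

Each detected S onset attaches the earliest pulse foot within
(s, s + 0.6 s] per channel; 0.6 s is sub-RR at resting heart rate and
is configurable. A foot attaches to at most one beat; unmatched entries
are missing values and drop out of calibration (never interpolated).
PTT is reported in ms as 1000·|t₁ − t₂|. The windowed PTT summaries —
variation = |Δ window-mean PTT / Δ window-mean BP| between successive
windows, variability = within-window SD of PTT, both reported
mean ± SD over windows — are explicit implementation definitions (the
underlying clinical quantities are cited, not defined, in the source
literature) and are labelled as such in output metadata.

## Hemodynamics

Pm uses trapezoidal quadrature (converges as O(fs⁻²) on smooth cycles);
Ps/Pd are the per-cycle extrema; cycle i spans [foot_i, foot_{i+1}).
K is dimensionless and affine-invariant. SV = 0.28/K²·(Ps−Pd)·T with
the 0.28 empirical constant; AC = SV/(Ps−Pd); TPR = Pm·T/SV. AC and
TPR are reported as ml/mmHg and mmHg·s/ml when the input is calibrated
pressure; from raw sensor voltages they inherit arbitrary units and the
report marks them uncalibrated.

## Calibration and validation

Default model is linear, BP = a·PTT + b, by ordinary least squares; a
logarithmic form BP = a·ln(PTT) + b is provided as well (both forms
appear in the PTT-BP literature; the linear form is the package
default). Fitting requires ≥ 2 distinct PTT values (rank-deficiency
error otherwise); the residual SD (n−2 denominator) is stored.
Bland–Altman differences are estimated − measured, SD uses n−1, limits
of agreement are mean ± 1.96·SD, and the AAMI verdict is pass iff
|mean| ≤ 5 mmHg **and** SD ≤ 8 mmHg, boundaries inclusive. Calibration
is per subject/session; in the bundled experiment validation reuses the
calibration points (as in cuff-referenced wearable studies), which
centers the mean difference by construction — the informative statistic
is the SD.

The bundled calibration experiment uses n = 250 paired points, slope
−0.5 mmHg/ms, intercept 180 mmHg, PTT ~ Normal(140, 15) ms and
reference noise Normal(0, 4) mmHg. The ±0.05 slope and ±8 mmHg
intercept recovery tolerances in the tests are the OLS sampling SDs at
these conditions (SE(â) = σ/(σ_PTT·√n) ≈ 0.017; 3σ ≈ 0.05).

## Triboelectric model

`tribo_charge`, `open_circuit_voltage` and `voltage_ratio` implement
the two-term single-electrode output model; the ratio contract enforces
equal shared parameters because only then does the ratio reduce to the
effective-area ratio. The box-knot geometry model counts one top-plane
area (15×15 mm²) per knotting layer for the apparent area and adds one
additional plane when the second layer makes an up-down contact pair —
this second-layer term is *inferred* from the printed geometry, the
unique choice consistent with the stated +33% estimate, and is flagged
as a model, not a measurement. Bench statistics: stored energy CU²/2;
peak areal power max(V²)/(R·A); pressure sensitivity as the OLS slope
over the linear range (default ≤ 0.44 kPa), in mV/Pa; resolution as the
smallest pressure-grid interval whose adjacent replicate V_oc
distributions separate by more than k = 2 pooled SDs ("distinctive
variation" is qualitative in the source; k = 2 is this package's
choice); hysteresis error as the maximum loading/unloading voltage gap
over the common pressure range (linear interpolation onto the union
grid) divided by the maximum loading voltage.

## Problem sizes

The default posture protocol (200/150/200 s at 400 Hz, ≈ 665 beats) is
the session size used throughout tests and examples; the calibration
experiment uses 250 pairs. These sizes give sub-second module runtimes
and percent-level Monte-Carlo precision, which matches the tolerances
asserted in the test suite.

## Known limitations

* Detection onsets carry a constant chain latency; absolute PAT/PTT
  values are therefore offset by a few samples unless a timing
  calibration is applied. All BP estimation is invariant to this.
* At heart rates above ≈ 100 bpm the quiescent-tail guarantee compresses
  systole below its physiological proportion, and pulse-chain latency
  grows by a few samples; the study protocols stay at 60–80 bpm.
* The z-score detector assumes a locally quiescent pre-event baseline;
  heavy baseline wander or motion artifact (not modelled) would require
  re-tuning lag/threshold.
* SV/AC/TPR from uncalibrated waveforms are unit-free indices, not
  clinical quantities.
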