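# knotbp

Cuffless blood-pressure estimation from pulse transit time, built around a
self-powered (triboelectric) box-knot pressure-pulse sensor paired with ECG
and PPG. The package is a tested, reusable pipeline for researchers in
wearable cardiovascular monitoring: it models the sensor's output, conditions
and fiducializes the three signal streams, extracts pulse transit times,
computes pulse-wave hemodynamics, and calibrates/validates a continuous BP
estimate — all exercised on a bundled synthetic-signal generator with
embedded ground truth, so no recordings or hardware are required.

## The method

**Sensor model.** A single-electrode triboelectric pair develops an
open-circuit voltage

    V = −Q_t/(A_a·ε)·(d_t + D) + σ·D/ε,     Q_t = A_e·(Ŵ₁ − Ŵ₂)

with effective (contact) area A_e and apparent (projected) area A_a. For two
units of identical materials, gap and apparent area, V_box/V_plane =
Q_t,box/Q_t,plane = A_e,box/A_e,plane — multi-stacked knot geometry buys
output in proportion to its stacked contact area.

**Timing chain.** Per beat, the ECG S wave is the cardiac fiducial. Pulse
feet at peripheral sites arrive PEP + PTT later (PEP: pre-ejection period).
The pressure channel is squared and low-passed (6 Hz → 3 Hz); the ECG is
over-filtered (4 Hz → 1 Hz) so each beat leaves one dominant trough. A
rolling z-score detector (lag, threshold, influence) converts each stream
into peak-defined codes in {−1, 0, +1}; the onset of each downward run is
the event, and PTT = |Δt| between the paired first-time pulses of two
streams, in ms.

**Hemodynamics.** From each pulse cycle p(t) with peak Ps, valley Pd,
duration T and mean Pm:

    K = (Pm − Pd)/(Ps − Pd)        SV = 0.28/K²·(Ps − Pd)·T
    AC = SV/(Ps − Pd)              TPR = Pm/SV·T

K is invariant to affine rescaling of p, hence valid on uncalibrated sensor
voltages.

**Calibration and validation.** BP = a·PTT + b fitted by ordinary least
squares (a log-form alternative is included); estimated vs. cuff-measured BP
is compared by Bland–Altman statistics against the AAMI device criteria
(|mean difference| ≤ 5 mmHg and SD ≤ 8 mmHg, inclusive).

## Worked example

```bash
python examples/05_bp_calibration.py
```

```
fitted calibration: SBP = -0.488·PTT + 178.5  (n=250, residual SD 3.92 mmHg)
Bland-Altman: mean diff -0.00 mmHg, SD 3.91 mmHg
limits of agreement: [-7.67, +7.67] mmHg
AAMI criteria (|mean| <= 5, SD <= 8 mmHg): PASS
```

250 paired (PTT, cuff SBP) points are drawn from SBP = −0.5·PTT + 180 with
4 mmHg measurement noise; least squares recovers the slope/intercept close
to the truth, and the Bland–Altman SD of (estimated − measured) tracks the
reference noise, inside both AAMI limits. The other scripts in `examples/`
walk through session simulation, conditioning + detection, PTT extraction,
hemodynamics and the sensor-geometry model the same way, each printing the
numbers it computes.

A full session-level run from the shell:

```bash
knotbp all --seed 7 --out out/
# -> session.csv, ground_truth.json, beats.csv, calibration.json,
#    bland_altman.json, hemodynamics.csv, run_config.json
```

## Library layout

| module                | contents                                              |
| --------------------- | ----------------------------------------------------- |
| `knotbp.synthwave`    | protocol/noise specs, ECG + pulse waveform generator with embedded ground truth |
| `knotbp.conditioning` | single-pole low-pass chains (causal / zero-phase), squaring, ECG over-filter |
| `knotbp.peakdetect`   | rolling z-score detector, peak-defined streams, onset extraction |
| `knotbp.ptt_engine`   | beat matching, PTT/HR computation, windowed PTT summaries |
| `knotbp.hemodynamics` | pulse cycles, K / SV / AC / TPR                       |
| `knotbp.bpcal`        | calibration fit, BP estimation, Bland–Altman, AAMI    |
| `knotbp.tribo`        | triboelectric output model, knot geometry, bench statistics |
| `knotbp.pipeline`     | stage bindings: detect → match → calibrate → validate |
| `knotbp.experiments`  | bundled desk-scale studies (calibration experiment, closure run) |
| `knotbp.cli`          | `knotbp` command: simulate/condition/detect/ptt/hemo/calibrate/estimate/report/all |

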