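"""Signal-conditioning chains for the pulse-pressure and ECG channels.

The pressure channel is digitized, squared, digitally amplified and then
smoothed by two cascaded first-order low-pass stages (6 Hz then 3 Hz),
mirroring the sensor firmware. The ECG channel is deliberately
*over-filtered* ("roughened") with a two-step low-pass cascade (4 Hz then
1 Hz) so that each beat collapses into a single smooth deflection from
which the S-wave onset can be picked up reliably.

All filters are first-order RC-discretized single-pole recursions with
unit DC gain. ``causal`` mode mimics the real-time microcontroller chain;
``zerophase`` applies the same filter forward then backward for offline
analysis where group delay matters. The group-delay difference between
the ECG and pulse chains in causal mode is not corrected — a constant
timing offset is absorbed by the PTT→BP calibration coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class FilterSpec:
    """First-order low-pass specification.

    cutoff_hz : -3 dB cutoff frequency in Hz; must satisfy 0 < fc < fs/2.
    order     : number of identical cascaded single-pole stages.
    mode      : "causal" (single pass) or "zerophase" (forward-backward).
    """

    cutoff_hz: float
    order: int = 1
    mode: str = "causal"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff_hz}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mode not in ("causal", "zerophase"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _alpha(fc: float, fs: float) -> float:
    # RC discretization: y[n] = a*x[n] + (1-a)*y[n-1], a = 1 - exp(-2*pi*fc/fs)
    return 1.0 - np.exp(-2.0 * np.pi * fc / fs)


def lowpass(x, fs: float, spec: FilterSpec) -> np.ndarray:
    """Single-pole recursive low-pass with exactly unit DC gain.

    Causal mode runs ``y[n] = a x[n] + (1-a) y[n-1]`` from zero initial
    state; zero-phase mode applies the causal filter forward then
    backward (squaring the magnitude response, cancelling the phase).
    """
    x = np.asarray(x, dtype=float)
    if spec.cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    if x.size == 0:
        return x.copy()
    a = _alpha(spec.cutoff_hz, fs)
    b, ap = [a], [1.0, -(1.0 - a)]
    if spec.mode == "causal":
        y = x
        for _ in range(spec.order):
            y = sps.lfilter(b, ap, y)
        return y
    # zero-phase: the forward-backward pass of the single pole has the
    # magnitude-squared response |H|^2 and no phase. Realizing it
    # spectrally (circular boundary) keeps the operator diagonal in
    # frequency, so zero-phase cascades commute exactly.
    w = 2.0 * np.pi * np.fft.rfftfreq(x.size)
    h = a / (1.0 - (1.0 - a) * np.exp(-1j * w))
    gain = np.abs(h) ** (2 * spec.order)
    return np.fft.irfft(np.fft.rfft(x) * gain, n=x.size)


SBKP_CUTOFFS_HZ = (6.0, 3.0)
ECG_CUTOFFS_HZ = (4.0, 1.0)


def condition_sbkp(
    x,
    fs: float,
    gain: float = 1.0,
    mode: str = "causal",
    cutoffs: tuple = SBKP_CUTOFFS_HZ,
) -> np.ndarray:
    """Pressure-pulse conditioning: square → gain → 6 Hz → 3 Hz low-pass.

    Squaring makes the output an even function of the input (a sign flip
    of the raw sensor voltage leaves the conditioned pulse unchanged) and
    guarantees a non-negative envelope.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    y = gain * x * x
    for fc in cutoffs:
        y = lowpass(y, fs, FilterSpec(fc, mode=mode))
    return y


def roughen_ecg(
    x, fs: float, mode: str = "causal", cutoffs: tuple = ECG_CUTOFFS_HZ
) -> np.ndarray:
    """Over-filter the ECG (4 Hz then 1 Hz low-pass) for S-foot detection.

    The cascade suppresses the sharp QRS spikes into one smooth dominant
    deflection per beat, trading morphology for a consistent fiducial.
    """
    if fs < 10.0:
        raise ValueError(f"sampling rate {fs} Hz too low for the over-filter cascade")
    y = x
    for fc in cutoffs:
        y = lowpass(y, fs, FilterSpec(fc, mode=mode))
    return y


def invert(x) -> np.ndarray:
    """Sign inversion, ``-x``. Applying it twice returns the original."""
    return -np.asarray(x, dtype=float)
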