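"""Pulse-wave hemodynamics: the K shape factor, stroke volume, arterial
compliance and total peripheral resistance.

For one cardiac cycle of a pressure-proportional pulse wave p(t) with
systolic peak Ps, diastolic valley Pd and duration T:

    Pm  = (1/T) ∫ p dt                  (mean pressure, trapezoidal)
    K   = (Pm − Pd) / (Ps − Pd)         (dimensionless waveform factor)
    SV  = 0.28 / K² · (Ps − Pd) · T     (stroke volume, ml)
    AC  = SV / (Ps − Pd)                (arterial compliance, ml/mmHg)
    TPR = Pm / SV · T                   (total peripheral resistance,
                                         mmHg·s/ml)

K depends only on the normalized area of the cycle, so it is invariant
to any affine rescaling p → αp + β with α > 0 — in particular it is
valid on uncalibrated sensor voltages. SV, AC and TPR, by contrast,
inherit the pressure units of the input: computed from uncalibrated
waveforms they carry arbitrary pressure units, which downstream reports
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SV_CONSTANT = 0.28  # ml·mmHg⁻¹·s⁻¹ empirical factor in the SV formula


class DegenerateCycleError(ValueError):
    """The cycle is flat (Ps = Pd): K is undefined."""


@dataclass
class PulseCycle:
    """One cardiac cycle of a pulse wave.

    ``samples`` are pressure-proportional values at rate ``fs``; the
    cycle duration is T = len(samples)/fs, the systolic peak Ps the
    cycle maximum and the diastolic valley Pd the cycle minimum.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empty cycle")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def T(self) -> float:
        return self.samples.size / self.fs

    @property
    def ps(self) -> float:
        return float(self.samples.max())

    @property
    def pd(self) -> float:
        return float(self.samples.min())


@dataclass
class HemoParams:
    """Per-cycle hemodynamic summary; ``calibrated`` records whether the
    pressure units are mmHg or arbitrary sensor units."""

    K: float
    Pm: float
    SV: float
    AC: float
    TPR: float
    T: float
    site: str = ""
    calibrated: bool = False


def mean_pressure(cycle: PulseCycle) -> float:
    """Trapezoidal time average of the cycle, (1/T)·∫p dt."""
    p = cycle.samples
    if p.size == 1:
        return float(p[0])
    return float(np.trapezoid(p, dx=1.0 / cycle.fs) / ((p.size - 1) / cycle.fs))


def compute_K(cycle: PulseCycle) -> float:
    """Waveform shape factor K = (Pm − Pd)/(Ps − Pd), in (0, 1)."""
    ps, pd = cycle.ps, cycle.pd
    if ps == pd:
        raise DegenerateCycleError("flat cycle: Ps equals Pd")
    return (mean_pressure(cycle) - pd) / (ps - pd)


def stroke_volume(K: float, ps: float, pd: float, T: float) -> float:
    """Stroke volume SV = 0.28/K² · (Ps − Pd) · T, in ml."""
    if K <= 0:
        raise ValueError("K must be positive")
    if ps <= pd:
        raise ValueError("need Ps > Pd")
    if T <= 0:
        raise ValueError("cycle duration must be positive")
    return SV_CONSTANT / K**2 * (ps - pd) * T


def arterial_compliance(sv: float, ps: float, pd: float) -> float:
    """Arterial compliance AC = SV/(Ps − Pd), in ml/mmHg."""
    if ps <= pd:
        raise ValueError("need Ps > Pd")
    return sv / (ps - pd)


def total_peripheral_resistance(pm: float, sv: float, T: float) -> float:
    """Total peripheral resistance TPR = Pm/SV · T, in mmHg·s/ml."""
    if sv <= 0:
        raise ValueError("stroke volume must be positive")
    return pm / sv * T


def cycle_params(cycle: PulseCycle, site: str = "", calibrated: bool = False) -> HemoParams:
    """All hemodynamic parameters of one cycle in a single pass."""
    pm = mean_pressure(cycle)
    k = compute_K(cycle)
    sv = stroke_volume(k, cycle.ps, cycle.pd, cycle.T)
    return HemoParams(
        K=k,
        Pm=pm,
        SV=sv,
        AC=arterial_compliance(sv, cycle.ps, cycle.pd),
        TPR=total_peripheral_resistance(pm, sv, cycle.T),
        T=cycle.T,
        site=site,
        calibrated=calibrated,
    )


def segment_cycles(pulse, foot_times, fs: float) -> list[PulseCycle]:
    """Cut a pulse signal into per-beat cycles at its foot times.

    Cycle i spans samples [foot_i, foot_{i+1}); fewer than two feet
    yield an empty list. Ps/Pd are taken per cycle by the
    :class:`PulseCycle` properties.
    """
    pulse = np.asarray(pulse, dtype=float)
    foot_times = np.asarray(foot_times, dtype=float)
    if foot_times.size < 2:
        return []
    if np.any(np.diff(foot_times) <= 0):
        raise ValueError("foot times must be strictly increasing")
    idx = np.round(foot_times * fs).astype(int)
    if idx[0] < 0 or idx[-1] > pulse.size:
        raise ValueError("foot times fall outside the signal")
    return [
        PulseCycle(samples=pulse[idx[i]: idx[i + 1]], fs=fs)
        for i in range(idx.size - 1)
        if idx[i + 1] > idx[i]
    ]
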