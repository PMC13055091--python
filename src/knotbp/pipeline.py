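"""End-to-end binding of the processing stages.

One function per stage boundary: condition + detect fiducials on a
session, match beats into PTT records, calibrate PTT against reference
BP, and validate the estimates. The constant onset latency of each
causal conditioning chain is *not* subtracted anywhere — it is identical
across beats and therefore absorbed by the calibration intercept, which
is also how the hardware pipeline behaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bpcal, conditioning, hemodynamics, peakdetect, ptt_engine
from .session import SignalSession


@dataclass
class Fiducials:
    """Detected event times (s) per channel."""

    s_feet: np.ndarray
    ppg_feet: np.ndarray
    sbkp_feet: np.ndarray


def detect_fiducials(
    session: SignalSession,
    params: peakdetect.PeakDetectorParams | None = None,
    mode: str = "causal",
) -> Fiducials:
    """Run each channel through its conditioning chain and detector.

    ECG: roughen (4 Hz → 1 Hz) → downward z-score onsets (S feet).
    Pulse channels: square + 6 Hz → 3 Hz → invert → downward onsets.
    """
    fs = session.fs
    if params is None:
        params = peakdetect.PeakDetectorParams.for_fs(fs)

    def pulse_feet(name: str) -> np.ndarray:
        y = conditioning.condition_sbkp(session[name], fs, mode=mode)
        stream = peakdetect.zscore_peaks(conditioning.invert(y), fs, params)
        return peakdetect.detect_pulse_feet(stream)

    s_feet = peakdetect.detect_s_feet(
        conditioning.roughen_ecg(session["ecg"], fs, mode=mode), fs, params
    )
    return Fiducials(
        s_feet=s_feet, ppg_feet=pulse_feet("ppg"), sbkp_feet=pulse_feet("sbkp")
    )


def beat_records(
    fiducials: Fiducials,
    max_latency: float = ptt_engine.DEFAULT_MAX_LATENCY_S,
) -> list[ptt_engine.BeatRecord]:
    """Match detected fiducials into per-beat PTT records."""
    return ptt_engine.match_beats(
        fiducials.s_feet, fiducials.ppg_feet, fiducials.sbkp_feet, max_latency
    )


def reference_sbp_at(protocol, times) -> np.ndarray:
    """Cuff-style reference systolic BP for each beat time (mmHg)."""
    return np.array([protocol.segment_at(t).systolic_bp for t in np.asarray(times)])


@dataclass
class ValidationBundle:
    """Calibration + agreement results of one session analysis."""

    model: bpcal.CalibrationModel
    bland_altman: bpcal.BlandAltmanResult
    aami: dict
    ptt_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    reference_bp: np.ndarray = field(default_factory=lambda: np.empty(0))
    estimated_bp: np.ndarray = field(default_factory=lambda: np.empty(0))


def calibrate_and_validate(
    ptt_ms,
    reference_bp,
    model_form: str = "linear",
    pair: str = "E-T",
) -> ValidationBundle:
    """Fit BP = a·PTT + b, estimate BP from PTT, and run the
    Bland–Altman/AAMI agreement check against the reference."""
    ptt_ms = np.asarray(ptt_ms, dtype=float)
    reference_bp = np.asarray(reference_bp, dtype=float)
    model = bpcal.fit_calibration(ptt_ms, reference_bp, model_form, pair=pair)
    est = bpcal.estimate_bp(ptt_ms, model)
    ba = bpcal.bland_altman(est, reference_bp)
    return ValidationBundle(
        model=model,
        bland_altman=ba,
        aami=bpcal.aami_check(ba),
        ptt_ms=ptt_ms,
        reference_bp=reference_bp,
        estimated_bp=est,
    )


def session_validation(
    session: SignalSession,
    protocol,
    pair: str = "E-T",
    model_form: str = "linear",
    params: peakdetect.PeakDetectorParams | None = None,
) -> ValidationBundle:
    """Full chain on one session: detect → match → calibrate → validate.

    The reference SBP of each matched beat comes from the protocol (the
    cuff schedule). Beats with a missing PTT are dropped, never
    interpolated.
    """
    fid = detect_fiducials(session, params=params)
    recs = beat_records(fid)
    attr = {"E-T": "ptt_et", "E-P": "ptt_ep", "P-T": "ptt_pt"}[pair]
    ptt, s_times = [], []
    for r in recs:
        v = getattr(r, attr)
        if v is not None:
            ptt.append(v)
            s_times.append(r.s_time)
    ref = reference_sbp_at(protocol, s_times)
    return calibrate_and_validate(ptt, ref, model_form=model_form, pair=pair)


def session_hemodynamics(
    session: SignalSession,
    fiducials: Fiducials | None = None,
    channel: str = "sbkp",
    params: peakdetect.PeakDetectorParams | None = None,
) -> list[hemodynamics.HemoParams]:
    """Per-cycle hemodynamic parameters from a pulse channel.

    Cycles are cut from the *raw* channel at the detected feet; the K
    shape factor is scale-invariant, but SV/AC/TPR inherit the channel's
    (uncalibrated) pressure units and are flagged accordingly.
    """
    if fiducials is None:
        fiducials = detect_fiducials(session, params=params)
    feet = {"ppg": fiducials.ppg_feet, "sbkp": fiducials.sbkp_feet}[channel]
    cycles = hemodynamics.segment_cycles(session[channel], feet, session.fs)
    return [
        hemodynamics.cycle_params(c, site=channel, calibrated=False) for c in cycles
    ]
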