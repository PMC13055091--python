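"""Synthetic ECG / PPG / pressure-pulse sessions with exhaustive ground truth.

The generator renders a multi-channel session the way the wearable
records one: a quasi-periodic ECG with PQRST morphology (the S deflection
is the per-beat global minimum and the timing fiducial), plus two pulse
channels — an optical PPG and the pressure-pulse (``sbkp``) channel —
whose cycle feet arrive after the S wave by the pre-ejection period (PEP)
plus a per-channel pulse transit time (PTT). The per-beat PTT of the
pressure channel is *derived from the target blood pressure* by inverting
the linear calibration BP = a·PTT + b, so every downstream stage can be
validated against embedded ground truth: the generator returns exactly
the event times and transit times it rendered.

Timing bookkeeping (all internal times in seconds; PTT reported in ms):

    pulse foot = S-wave time + PEP + PTT
    PAT        = PEP + PTT        (pulse arrival time, S wave → foot)

The PPG foot lags the pressure-channel foot by a fixed site delay
(fingertip vs. neck path difference); the delay is a synthetic default,
not a physiological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolSegment",
    "SessionProtocol",
    "NoiseSpec",
    "EcgMorphology",
    "PulseShape",
    "GroundTruth",
    "ecg_waveform",
    "pulse_waveform",
    "simulate_session",
    "DegenerateModelError",
    "InfeasibleProtocolError",
    "AliasingError",
]


class DegenerateModelError(ValueError):
    """The calibration slope is zero: BP cannot be inverted to a PTT."""


class InfeasibleProtocolError(ValueError):
    """A protocol segment implies a non-positive pulse transit time."""


class AliasingError(ValueError):
    """Sampling rate too low for the narrowest waveform kernel."""


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-condition stretch of a recording session."""

    label: str
    duration: float  # seconds
    systolic_bp: float  # mmHg
    diastolic_bp: float  # mmHg
    heart_rate: float  # bpm

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if not 30.0 <= self.heart_rate <= 220.0:
            raise ValueError(f"heart rate {self.heart_rate} bpm outside [30, 220]")
        if not self.systolic_bp > self.diastolic_bp > 0:
            raise ValueError("need systolic > diastolic > 0")


@dataclass(frozen=True)
class SessionProtocol:
    """A sequence of protocol segments at a fixed sampling rate.

    The default mirrors a posture protocol: sitting, lying and standing
    for 200, 150 and 200 s with stepwise blood-pressure changes.
    """

    segments: tuple = ()
    sampling_rate: float = 400.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "segments", tuple(self.segments))

    @classmethod
    def posture_default(cls, sampling_rate: float = 400.0) -> "SessionProtocol":
        return cls(
            segments=(
                ProtocolSegment("sitting", 200.0, 120.0, 80.0, 72.0),
                ProtocolSegment("lying", 150.0, 110.0, 74.0, 64.0),
                ProtocolSegment("standing", 200.0, 128.0, 84.0, 80.0),
            ),
            sampling_rate=sampling_rate,
        )

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment_at(self, t: float) -> ProtocolSegment:
        edge = 0.0
        for seg in self.segments:
            edge += seg.duration
            if t < edge:
                return seg
        return self.segments[-1]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive artifact model applied to every channel.

    White Gaussian noise (SD in channel units), sinusoidal baseline
    wander and powerline interference. The same spec with the same seed
    reproduces bit-identical sessions. Defaults emulate a reasonably
    clean wearable recording; ``NoiseSpec.none()`` disables everything.
    """

    white_sd: float = 0.01
    baseline_wander_amp: float = 0.05
    baseline_wander_hz: float = 0.25
    powerline_amp: float = 0.005
    powerline_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("white_sd", "baseline_wander_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(white_sd=0.0, baseline_wander_amp=0.0, powerline_amp=0.0)

    def render(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(n) / fs
        out = np.zeros(n)
        if self.white_sd > 0:
            out += rng.normal(0.0, self.white_sd, n)
        if self.baseline_wander_amp > 0:
            out += self.baseline_wander_amp * np.sin(
                2 * np.pi * self.baseline_wander_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if self.powerline_amp > 0:
            out += self.powerline_amp * np.sin(
                2 * np.pi * self.powerline_hz * t + rng.uniform(0, 2 * np.pi)
            )
        return out


@dataclass(frozen=True)
class EcgMorphology:
    """Sum-of-Gaussians ECG beat: one (amplitude, offset, width) triple
    per deflection, offsets relative to the R peak in seconds.

    The S wave is rendered deep and narrow so it is both the per-beat
    global minimum and a sharp timing fiducial. ``tachycardia`` adds an
    extra positive bump riding on the T wave, emulating the extra T-wave
    peak seen at ~118 bpm.
    """

    waves: tuple = (
        ("P", 0.06, -0.16, 0.018),
        ("Q", -0.04, -0.020, 0.008),
        ("R", 1.00, 0.0, 0.009),
        ("S", -1.60, 0.025, 0.011),
        ("T", 0.12, 0.22, 0.030),
    )
    tachycardia: bool = False
    tachy_bump: tuple = ("T2", 0.12, 0.30, 0.025)

    @property
    def s_offset(self) -> float:
        for name, _amp, off, _w in self.waves:
            if name == "S":
                return off
        raise ValueError("morphology has no S wave")

    def active_waves(self) -> list:
        waves = list(self.waves)
        if self.tachycardia:
            waves.append(self.tachy_bump)
        return waves

    def min_width(self) -> float:
        widths = [w for _n, a, _o, w in self.active_waves() if a != 0]
        return min(widths) if widths else np.inf


def ecg_waveform(
    beat_times,
    morphology: EcgMorphology | None = None,
    fs: float = 400.0,
    duration: float | None = None,
) -> np.ndarray:
    """Render an ECG as localized Gaussian kernels around each R time.

    Raises :class:`AliasingError` when the narrowest active kernel would
    span less than one sample (fs · width < 1).
    """
    morphology = morphology or EcgMorphology()
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size > 1 and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    if fs * morphology.min_width() < 1.0:
        raise AliasingError(
            f"fs={fs} Hz under-samples a kernel of width {morphology.min_width()} s"
        )
    if duration is None:
        duration = (float(beat_times[-1]) + 1.0) if beat_times.size else 1.0
    t = np.arange(int(round(duration * fs))) / fs
    out = np.zeros_like(t)
    for _name, amp, off, width in morphology.active_waves():
        if amp == 0:
            continue
        for tb in beat_times:
            c = tb + off
            lo = np.searchsorted(t, c - 6 * width)
            hi = np.searchsorted(t, c + 6 * width)
            out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return out


@dataclass(frozen=True)
class PulseShape:
    """Asymmetric pulse-cycle template: gamma-like rise/decay plus an
    additive Gaussian dicrotic bump.

    ``peak_frac`` is the time-to-percussion-peak as a fraction of the
    cycle; ``steepness`` the gamma exponent (larger = sharper foot);
    ``dicrotic_*`` place the secondary (D-) wave. The template is
    normalized to [0, 1] per cycle, so the rendered cycle spans exactly
    [Pd, Ps] up to sample quantization.
    """

    peak_s: float = 0.12
    steepness: float = 1.6
    dicrotic_amp: float = 0.22
    dicrotic_s: float = 0.34
    dicrotic_width_s: float = 0.038
    fade_start_s: float = 0.40
    fade_end_s: float = 0.50
    quiescent_tail_s: float = 0.40  # flat end-diastole per cycle, HR-independent
    min_systole_scale: float = 0.5
    max_systole_scale: float = 1.5
    min_cycle_s: float = 60.0 / 220.0  # shortest supported RR interval

    def template(self, n: int, fs: float) -> np.ndarray:
        """Unit-normalized cycle of ``n`` samples, value 0 at the foot.

        Systolic timing (time-to-peak, dicrotic position, fade) is set
        in absolute seconds — as in real pulses, where systole barely
        shortens with heart rate while diastole absorbs the RR change.
        A raised-cosine fade drives the tail to exactly the diastolic
        baseline, so the last ``quiescent_tail_s`` of every cycle is
        genuinely quiescent regardless of heart rate: the systolic
        program stretches or compresses (within the scale bounds) so
        that diastole, not systole, absorbs RR changes — as in real
        pulses, where systole shortens only moderately under
        tachycardia.
        """
        tau = np.arange(n) / fs
        T = n / fs
        scale = np.clip(
            (T - self.quiescent_tail_s) / self.fade_end_s,
            self.min_systole_scale,
            self.max_systole_scale,
        )
        tp, k = self.peak_s * scale, self.steepness
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (tau / tp) ** k * np.exp(k * (1.0 - tau / tp))
        g[0] = 0.0
        u = g + self.dicrotic_amp * np.exp(
            -0.5 * ((tau - self.dicrotic_s * scale) / (self.dicrotic_width_s * scale)) ** 2
        )
        f0, f1 = self.fade_start_s * scale, self.fade_end_s * scale
        fade = 0.5 * (1.0 + np.cos(np.pi * np.clip((tau - f0) / (f1 - f0), 0.0, 1.0)))
        u = u * fade
        return u / u.max()


def pulse_waveform(
    foot_times,
    ps,
    pd,
    shape: PulseShape | None = None,
    fs: float = 400.0,
    duration: float | None = None,
) -> np.ndarray:
    """Render a pulse wave with one cycle per foot time.

    ``ps``/``pd`` may be scalars or per-cycle arrays; each cycle rises
    from its diastolic value ``pd`` at the foot to the percussion peak
    ``ps`` and decays through the dicrotic bump. The samples before the
    first foot and after the last cycle sit at the adjacent ``pd``.
    The last cycle reuses the previous cycle's duration (0.8 s for a
    single foot).
    """
    shape = shape or PulseShape()
    foot_times = np.asarray(foot_times, dtype=float)
    n_beats = foot_times.size
    if n_beats == 0:
        raise ValueError("need at least one foot time")
    if np.any(np.diff(foot_times) <= 0):
        raise ValueError("foot times must be strictly increasing")
    spacing = np.diff(foot_times)
    if np.any(spacing < shape.min_cycle_s):
        raise ValueError(
            f"foot spacing {spacing.min():.3f} s below the minimum cycle "
            f"width {shape.min_cycle_s:.3f} s"
        )
    ps = np.broadcast_to(np.asarray(ps, dtype=float), (n_beats,))
    pd_ = np.broadcast_to(np.asarray(pd, dtype=float), (n_beats,))
    if np.any(ps <= pd_):
        raise ValueError("need ps > pd for every cycle")

    durations = np.empty(n_beats)
    durations[:-1] = spacing
    durations[-1] = spacing[-1] if n_beats > 1 else 0.8
    if duration is None:
        duration = float(foot_times[-1] + durations[-1])
    n = int(round(duration * fs))
    out = np.empty(n)
    out[: min(n, int(round(foot_times[0] * fs)))] = pd_[0]

    for i in range(n_beats):
        i0 = int(round(foot_times[i] * fs))
        i1 = int(round((foot_times[i] + durations[i]) * fs))
        i0c, i1c = min(i0, n), min(i1, n)
        if i1 <= i0 or i0c >= n:
            continue
        u = shape.template(i1 - i0, fs)
        out[i0c:i1c] = pd_[i] + (ps[i] - pd_[i]) * u[: i1c - i0c]
    tail = int(round((foot_times[-1] + durations[-1]) * fs))
    if tail < n:
        out[tail:] = pd_[-1]
    return out


@dataclass
class GroundTruth:
    """Everything the generator embedded, exactly as rendered.

    Per beat: S-wave times, per-channel foot times, pulse arrival times
    (``pat = pep + ptt``) and transit times in ms; per segment: the true
    systolic/diastolic pressures and heart rate.
    """

    s_wave_times: np.ndarray  # s, per beat
    ppg_foot_times: np.ndarray  # s
    sbkp_foot_times: np.ndarray  # s
    ptt_et_ms: np.ndarray  # ECG→pressure-channel transit time, per beat
    ptt_ep_ms: np.ndarray  # ECG→PPG transit time, per beat
    pep_s: float
    beat_sbp: np.ndarray  # mmHg, per beat
    beat_dbp: np.ndarray
    beat_hr: np.ndarray  # bpm, per beat (from the protocol)
    segment_labels: list = field(default_factory=list)
    segment_sbp: np.ndarray = field(default_factory=lambda: np.empty(0))
    segment_dbp: np.ndarray = field(default_factory=lambda: np.empty(0))
    segment_hr: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def pat_et(self) -> np.ndarray:
        """S-wave → pressure-channel foot interval, seconds per beat."""
        return self.pep_s + self.ptt_et_ms / 1000.0

    @property
    def pat_ep(self) -> np.ndarray:
        """S-wave → PPG foot interval, seconds per beat."""
        return self.pep_s + self.ptt_ep_ms / 1000.0

    def to_dict(self) -> dict:
        return {
            "s_wave_times": self.s_wave_times.tolist(),
            "ppg_foot_times": self.ppg_foot_times.tolist(),
            "sbkp_foot_times": self.sbkp_foot_times.tolist(),
            "ptt_et_ms": self.ptt_et_ms.tolist(),
            "ptt_ep_ms": self.ptt_ep_ms.tolist(),
            "pep_s": self.pep_s,
            "beat_sbp": self.beat_sbp.tolist(),
            "beat_dbp": self.beat_dbp.tolist(),
            "beat_hr": self.beat_hr.tolist(),
            "segments": {
                "labels": list(self.segment_labels),
                "sbp": self.segment_sbp.tolist(),
                "dbp": self.segment_dbp.tolist(),
                "hr": self.segment_hr.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        seg = d.get("segments", {})
        return cls(
            s_wave_times=np.asarray(d["s_wave_times"], float),
            ppg_foot_times=np.asarray(d["ppg_foot_times"], float),
            sbkp_foot_times=np.asarray(d["sbkp_foot_times"], float),
            ptt_et_ms=np.asarray(d["ptt_et_ms"], float),
            ptt_ep_ms=np.asarray(d["ptt_ep_ms"], float),
            pep_s=float(d["pep_s"]),
            beat_sbp=np.asarray(d["beat_sbp"], float),
            beat_dbp=np.asarray(d["beat_dbp"], float),
            beat_hr=np.asarray(d["beat_hr"], float),
            segment_labels=list(seg.get("labels", [])),
            segment_sbp=np.asarray(seg.get("sbp", []), float),
            segment_dbp=np.asarray(seg.get("dbp", []), float),
            segment_hr=np.asarray(seg.get("hr", []), float),
        )


#: default pre-ejection period, seconds (constant per subject, configurable)
DEFAULT_PEP_S = 0.030
#: extra fingertip-vs-neck arrival delay of the PPG foot, ms (synthetic default)
DEFAULT_PPG_SITE_DELAY_MS = 50.0
#: pressure-proportional channel scale: rendered volts = mmHg / this
PRESSURE_SCALE = 100.0
#: PPG rendering: DC perfusion baseline and pulsatile (AC) amplitude.
#: Real PPG rides on a large DC component; keeping the relative
#: modulation comparable to the pressure channel also gives both pulse
#: chains the same conditioning response shape.
PPG_DC = 1.0
PPG_AC = 0.4


def simulate_session(
    protocol: SessionProtocol,
    noise: NoiseSpec,
    calib,
    morphology: EcgMorphology | None = None,
    pulse_shape: PulseShape | None = None,
    pep_s: float = DEFAULT_PEP_S,
    ppg_site_delay_ms: float = DEFAULT_PPG_SITE_DELAY_MS,
    rr_jitter_frac: float = 0.0,
):
    """Render a full session and the ground truth embedded in it.

    Per beat the pressure-channel PTT is the inverse of the linear
    calibration, ``PTT = (SBP − b)/a`` in ms, and the pulse foot lands at
    ``S-wave time + PEP + PTT``. The PPG foot lags by a fixed site delay.
    ``rr_jitter_frac`` adds seeded uniform ±fractional RR jitter.

    Returns ``(SignalSession, GroundTruth)``.
    """
    from .session import SignalSession

    if calib.a == 0:
        raise DegenerateModelError("calibration slope a must be nonzero")
    morphology = morphology or EcgMorphology()
    pulse_shape = pulse_shape or PulseShape()
    fs = protocol.sampling_rate
    total = protocol.duration
    rng = np.random.default_rng(noise.seed)

    # feasibility: every segment must map to a positive transit time
    for seg in protocol.segments:
        if (seg.systolic_bp - calib.b) / calib.a <= 0:
            raise InfeasibleProtocolError(
                f"segment {seg.label!r}: SBP {seg.systolic_bp} mmHg implies "
                "a non-positive PTT under the given calibration"
            )

    # beat train: piecewise-constant HR per segment, optional RR jitter
    r_times, s_off = [], morphology.s_offset
    t = 0.5  # settle-in before the first beat
    margin = 1.0  # keep whole cycles inside the rendered grid
    while t < total - margin:
        r_times.append(t)
        seg = protocol.segment_at(t)
        rr = 60.0 / seg.heart_rate
        if rr_jitter_frac > 0:
            rr *= 1.0 + rng.uniform(-rr_jitter_frac, rr_jitter_frac)
        t += rr
    r_times = np.asarray(r_times)
    if r_times.size < 2:
        raise InfeasibleProtocolError("protocol too short for two beats")

    segs = [protocol.segment_at(tb) for tb in r_times]
    beat_sbp = np.array([s.systolic_bp for s in segs])
    beat_dbp = np.array([s.diastolic_bp for s in segs])
    beat_hr = np.array([s.heart_rate for s in segs])
    ptt_et_ms = (beat_sbp - calib.b) / calib.a
    ptt_ep_ms = ptt_et_ms + ppg_site_delay_ms
    s_times = r_times + s_off
    sbkp_feet = s_times + pep_s + ptt_et_ms / 1000.0
    ppg_feet = s_times + pep_s + ptt_ep_ms / 1000.0

    ecg = ecg_waveform(r_times, morphology, fs, duration=total)
    ppg = pulse_waveform(
        ppg_feet, PPG_DC + PPG_AC, PPG_DC, pulse_shape, fs, duration=total
    )
    sbkp = pulse_waveform(
        sbkp_feet,
        beat_sbp / PRESSURE_SCALE,
        beat_dbp / PRESSURE_SCALE,
        pulse_shape,
        fs,
        duration=total,
    )
    n = len(ecg)
    channels = {}
    for name, clean in (("ecg", ecg), ("ppg", ppg), ("sbkp", sbkp)):
        channels[name] = clean + noise.render(n, fs, rng)

    truth = GroundTruth(
        s_wave_times=s_times,
        ppg_foot_times=ppg_feet,
        sbkp_foot_times=sbkp_feet,
        ptt_et_ms=ptt_et_ms,
        ptt_ep_ms=ptt_ep_ms,
        pep_s=pep_s,
        beat_sbp=beat_sbp,
        beat_dbp=beat_dbp,
        beat_hr=beat_hr,
        segment_labels=[s.label for s in protocol.segments],
        segment_sbp=np.array([s.systolic_bp for s in protocol.segments]),
        segment_dbp=np.array([s.diastolic_bp for s in protocol.segments]),
        segment_hr=np.array([s.heart_rate for s in protocol.segments]),
    )
    return SignalSession(fs=fs, channels=channels), truth
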