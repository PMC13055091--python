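"""Robust z-score peak detection producing peak-defined signals.

Each sample of the input is coded −1 (downward peak), 0 (null) or +1
(upward peak) by comparing it against the mean and standard deviation of
an influence-damped rolling history of the previous ``lag`` samples: a
sample deviating by more than ``threshold`` rolling standard deviations
is flagged, and flagged samples enter the history only with weight
``influence`` so a sustained peak does not inflate the baseline
statistics. Event times are taken at the *onset* of each flagged run
(first-time-pulse semantics): the first flagged sample marks the event,
and runs closer than the refractory period are merged keeping the
earliest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: relative sigma floor, as a fraction of the signal's peak-to-peak range
SIGMA_FLOOR_FRAC = 1e-9


@dataclass(frozen=True)
class PeakDetectorParams:
    """Tuning of the rolling z-score detector.

    lag        : history length in samples (>= 2).
    threshold  : flag deviations beyond this many rolling SDs.
    influence  : weight in [0, 1] with which flagged samples update the
                 history (0 freezes the baseline during a peak).
    refractory : minimum separation of same-polarity events, seconds.
    polarity   : which flagged runs become events: "down", "up" or "both".
    """

    lag: int = 100
    threshold: float = 3.5
    influence: float = 0.1
    refractory: float = 0.25
    polarity: str = "down"

    def __post_init__(self) -> None:
        if self.lag < 2:
            raise ValueError("lag must be >= 2 samples")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0.0 <= self.influence <= 1.0:
            raise ValueError("influence must lie in [0, 1]")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.polarity not in ("down", "up", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @classmethod
    def for_fs(cls, fs: float, lag_s: float = 0.25, **kw) -> "PeakDetectorParams":
        """Defaults with the lag window expressed in seconds (0.25 s)."""
        return cls(lag=max(2, int(round(lag_s * fs))), **kw)


@dataclass
class PeakStream:
    """Per-sample peak codes in {−1, 0, +1} plus the detector settings."""

    codes: np.ndarray
    fs: float
    params: PeakDetectorParams = field(default_factory=PeakDetectorParams)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("codes must lie in {-1, 0, +1}")

    def run_onsets(self, code: int) -> np.ndarray:
        """Sample indices where a run of ``code`` begins."""
        hit = self.codes == code
        onset = hit & ~np.concatenate(([False], hit[:-1]))
        return np.flatnonzero(onset)

    @property
    def event_times(self) -> np.ndarray:
        """Onset times (s) of the runs selected by the configured polarity."""
        want = {"down": (-1,), "up": (1,), "both": (-1, 1)}[self.params.polarity]
        idx = np.sort(np.concatenate([self.run_onsets(c) for c in want]))
        return idx / self.fs


def zscore_peaks(x, fs: float, params: PeakDetectorParams | None = None) -> PeakStream:
    """Run the rolling z-score detector over a signal.

    The first ``lag`` samples are coded 0 (they only seed the history).
    A sigma floor of ``SIGMA_FLOOR_FRAC`` times the signal range keeps a
    flat history from dividing by zero; a constant signal yields all
    zeros rather than an exception.
    """
    if params is None:
        params = PeakDetectorParams.for_fs(fs)
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= params.lag:
        raise ValueError(f"signal length {n} must exceed lag {params.lag}")

    ptp = float(np.ptp(x))
    floor = SIGMA_FLOOR_FRAC * ptp if ptp > 0 else np.finfo(float).tiny
    lag, thr, infl = params.lag, params.threshold, params.influence

    codes = np.zeros(n, dtype=np.int8)
    buf = x[:lag].astype(float).copy()  # circular buffer of the damped history
    pos = 0
    s = float(np.sum(buf))  # running sum / sum of squares over the window
    q = float(np.sum(buf * buf))
    for i in range(lag, n):
        mu = s / lag
        var = q / lag - mu * mu
        sd = max(np.sqrt(var) if var > 0 else 0.0, floor)
        dev = x[i] - mu
        if dev > thr * sd:
            codes[i] = 1
        elif dev < -thr * sd:
            codes[i] = -1
        if codes[i] != 0:
            new = infl * x[i] + (1.0 - infl) * buf[(pos - 1) % lag]
        else:
            new = x[i]
        old = buf[pos]
        buf[pos] = new
        pos = (pos + 1) % lag
        s += new - old
        q += new * new - old * old
    return PeakStream(codes=codes, fs=fs, params=params)


def _merge_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Drop events closer than ``refractory`` to the last kept one."""
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory:
            kept.append(float(t))
    return np.asarray(kept)


def detect_pulse_feet(stream: PeakStream, fs: float | None = None) -> np.ndarray:
    """Extract pulse-foot times (s) from the −1 runs of a peak stream.

    The onset of each downward run is the foot; runs closer than the
    refractory period collapse onto the earliest.
    """
    del fs  # the stream already carries its sampling rate
    onsets = stream.run_onsets(-1) / stream.fs
    return _merge_refractory(onsets, stream.params.refractory)


def detect_s_feet(
    ecg_roughened, fs: float, params: PeakDetectorParams | None = None
) -> np.ndarray:
    """Detect per-beat S-wave onsets on an over-filtered ECG.

    Applies the z-score detector with downward polarity and extracts run
    onsets exactly as :func:`detect_pulse_feet`.
    """
    if params is None:
        params = PeakDetectorParams.for_fs(fs)
    if params.polarity != "down":
        params = PeakDetectorParams(
            lag=params.lag,
            threshold=params.threshold,
            influence=params.influence,
            refractory=params.refractory,
            polarity="down",
        )
    stream = zscore_peaks(ecg_roughened, fs, params)
    return detect_pulse_feet(stream)
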