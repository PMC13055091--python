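"""Multi-channel physiological signal sessions and their CSV on-disk format.

A session is a set of synchronously sampled channels (ECG, PPG and the
pressure-pulse channel, called ``sbkp`` after the box-knot sensor) on a
uniform time grid. On disk a session is a plain CSV with header
``time_s,ecg,ppg,sbkp`` and one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("ecg", "ppg", "sbkp")

#: maximum tolerated jitter of the time grid, in seconds
TIME_JITTER_TOL = 1e-6


class SessionFormatError(ValueError):
    """Raised when a session file violates the expected format."""


@dataclass
class SignalSession:
    """Synchronized multi-channel waveforms at a fixed sampling rate.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    channels : dict
        Mapping from channel name to a 1-D float array. All channels
        must have equal length.
    """

    fs: float
    channels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def read_session(path) -> SignalSession:
    """Read a session CSV (header ``time_s,ecg,ppg,sbkp``).

    The time column must be a uniform, strictly increasing grid; the
    sampling rate is inferred from it. Grids with more than 1 microsecond
    of jitter, missing columns, or NaN samples are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", *CHANNELS) if c not in df.columns]
    if missing:
        raise SessionFormatError(f"missing column(s) {missing} in {path}")
    if len(df) < 2:
        raise SessionFormatError("session needs at least 2 samples")
    if df[list(("time_s", *CHANNELS))].isna().any().any():
        raise SessionFormatError("session contains NaN values")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SessionFormatError("time column is not strictly increasing")
    if np.ptp(dt) > TIME_JITTER_TOL:
        raise SessionFormatError(
            f"non-uniform time grid (jitter {np.ptp(dt):.3g} s exceeds "
            f"{TIME_JITTER_TOL} s)"
        )
    fs = 1.0 / float(np.mean(dt))
    return SignalSession(fs=fs, channels={c: df[c].to_numpy(float) for c in CHANNELS})


def write_session(session: SignalSession, path) -> None:
    """Write a session to CSV so that :func:`read_session` round-trips it."""
    df = pd.DataFrame({"time_s": session.time})
    for c in CHANNELS:
        df[c] = session.channels[c]
    df.to_csv(path, index=False, float_format="%.9g")
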