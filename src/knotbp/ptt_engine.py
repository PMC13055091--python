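"""Beat matching and pulse-transit-time extraction across sensor streams.

Each detected S-wave onset is paired with the earliest subsequent pulse
foot per channel (the "first-time-pulse" of that beat); PTT is the
absolute time difference between two such fiducials, reported in ms.
Missing feet are recorded as missing values, never raised: dropped beats
simply do not enter the calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default matching window, seconds (sub-RR at resting heart rate)
DEFAULT_MAX_LATENCY_S = 0.6


@dataclass
class BeatRecord:
    """One matched cardiac beat across the ECG, PPG and pressure streams."""

    s_time: float  # s
    ppg_foot: float | None = None  # s
    sbkp_foot: float | None = None  # s
    ptt_ep: float | None = None  # ms, ECG→PPG
    ptt_et: float | None = None  # ms, ECG→pressure channel
    ptt_pt: float | None = None  # ms, PPG→pressure channel
    hr: float | None = None  # bpm, from the preceding RR interval


@dataclass
class PttSummary:
    """Windowed PTT statistics: variation (ms/mmHg) and variability (ms).

    ``variation`` is the per-window |ΔPTT/ΔBP| of window means between
    consecutive windows; ``variability`` the per-window SD of PTT. Both
    are reported as (mean, SD) over windows. These windowed definitions
    are an explicit implementation choice of this package.
    """

    variation_mean: float
    variation_sd: float
    variability_mean: float
    variability_sd: float
    n_windows: int
    skipped_windows: int = 0


def compute_ptt(t1: float, t2: float) -> float:
    """PTT in ms: 1000·|t1 − t2|. Symmetric in its arguments."""
    if not (math.isfinite(t1) and math.isfinite(t2)):
        raise ValueError("fiducial times must be finite")
    return 1000.0 * abs(t1 - t2)


def heart_rate(s_times) -> np.ndarray:
    """Instantaneous heart rate, 60/ΔRR bpm per successive pair."""
    s_times = np.asarray(s_times, dtype=float)
    if s_times.size < 2:
        return np.empty(0)
    dt = np.diff(s_times)
    if np.any(dt <= 0):
        raise ValueError("event times must be strictly increasing")
    return 60.0 / dt


def _attach(s_times: np.ndarray, feet: np.ndarray, max_latency: float) -> list:
    """Earliest foot in (s, s+max_latency] per beat; each foot used once."""
    out: list[float | None] = []
    j = 0
    for s in s_times:
        while j < feet.size and feet[j] <= s:
            j += 1
        if j < feet.size and feet[j] - s <= max_latency:
            out.append(float(feet[j]))
            j += 1
        else:
            out.append(None)
    return out


def match_beats(
    s_times,
    ppg_feet,
    sbkp_feet,
    max_latency: float = DEFAULT_MAX_LATENCY_S,
) -> list[BeatRecord]:
    """Pair every S-wave onset with its first-time pulse per channel.

    For each S time the earliest foot within ``(s, s + max_latency]`` of
    each pulse channel is attached; a foot attaches to at most one beat,
    and unmatched fiducials are left missing.
    """
    s_times = np.asarray(s_times, dtype=float)
    for name, arr in (("s_times", s_times),
                      ("ppg_feet", np.asarray(ppg_feet, float)),
                      ("sbkp_feet", np.asarray(sbkp_feet, float))):
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    ppg_feet = np.asarray(ppg_feet, dtype=float)
    sbkp_feet = np.asarray(sbkp_feet, dtype=float)

    ppg_match = _attach(s_times, ppg_feet, max_latency)
    sbkp_match = _attach(s_times, sbkp_feet, max_latency)
    hrs = heart_rate(s_times) if s_times.size >= 2 else np.empty(0)

    records = []
    for i, s in enumerate(s_times):
        p, k = ppg_match[i], sbkp_match[i]
        rec = BeatRecord(
            s_time=float(s),
            ppg_foot=p,
            sbkp_foot=k,
            hr=float(hrs[i - 1]) if i >= 1 else None,
        )
        if p is not None:
            rec.ptt_ep = compute_ptt(s, p)
        if k is not None:
            rec.ptt_et = compute_ptt(s, k)
        if p is not None and k is not None:
            rec.ptt_pt = compute_ptt(p, k)
        records.append(rec)
    return records


def records_frame(records: list[BeatRecord]) -> pd.DataFrame:
    """Per-beat table, ready for CSV export."""
    return pd.DataFrame(
        {
            "beat_idx": np.arange(len(records)),
            "s_time_s": [r.s_time for r in records],
            "ptt_ep_ms": [r.ptt_ep for r in records],
            "ptt_et_ms": [r.ptt_et for r in records],
            "ptt_pt_ms": [r.ptt_pt for r in records],
            "hr_bpm": [r.hr for r in records],
        }
    )


def ptt_summaries(ptts, bps, window: int = 10) -> PttSummary:
    """Windowed PTT variation and variability over aligned series.

    The series are cut into consecutive windows of ``window`` beats.
    Variation: |Δ window-mean PTT / Δ window-mean BP| between successive
    windows (windows with ΔBP = 0 are skipped and counted); variability:
    within-window SD of PTT. Both summarized as mean ± SD over windows.
    """
    ptts = np.asarray(ptts, dtype=float)
    bps = np.asarray(bps, dtype=float)
    if ptts.shape != bps.shape:
        raise ValueError("ptt and bp series must be aligned")
    if window < 1:
        raise ValueError("window must be >= 1 beat")
    n_win = ptts.size // window
    if n_win < 2:
        raise ValueError("need at least two full windows")
    pm = ptts[: n_win * window].reshape(n_win, window)
    bm = bps[: n_win * window].reshape(n_win, window)
    mean_ptt, mean_bp = pm.mean(axis=1), bm.mean(axis=1)
    sd_ptt = pm.std(axis=1, ddof=1) if window > 1 else np.zeros(n_win)

    d_ptt, d_bp = np.diff(mean_ptt), np.diff(mean_bp)
    ok = d_bp != 0
    variations = np.abs(d_ptt[ok] / d_bp[ok])
    if variations.size == 0:
        raise ValueError("all windows have zero BP change; variation undefined")
    return PttSummary(
        variation_mean=float(np.mean(variations)),
        variation_sd=float(np.std(variations, ddof=1)) if variations.size > 1 else 0.0,
        variability_mean=float(np.mean(sd_ptt)),
        variability_sd=float(np.std(sd_ptt, ddof=1)) if n_win > 1 else 0.0,
        n_windows=n_win,
        skipped_windows=int(np.sum(~ok)),
    )
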