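"""Reference synthetic experiments bundled with the package.

These are the desk-scale study designs the test-suite and the
reproduction script run: a calibration/validation experiment at the
paired-observation level (~250 cuff/PTT points under the linear model
with measurement noise), and a waveform-level ground-truth closure run
of the full detection pipeline on a noiseless session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pipeline
from .bpcal import CalibrationModel
from .synthwave import NoiseSpec, SessionProtocol, simulate_session

#: study conditions of the synthetic calibration experiment
CALIB_N_POINTS = 250
CALIB_SLOPE = -0.5  # mmHg per ms
CALIB_INTERCEPT = 180.0  # mmHg
CALIB_PTT_MEAN_MS = 140.0
CALIB_PTT_SD_MS = 15.0
CALIB_BP_NOISE_SD = 4.0  # mmHg cuff/measurement noise


def synthetic_calibration_experiment(
    n: int = CALIB_N_POINTS,
    a: float = CALIB_SLOPE,
    b: float = CALIB_INTERCEPT,
    ptt_mean: float = CALIB_PTT_MEAN_MS,
    ptt_sd: float = CALIB_PTT_SD_MS,
    noise_sd: float = CALIB_BP_NOISE_SD,
    seed: int = 42,
    model_form: str = "linear",
) -> pipeline.ValidationBundle:
    """Paired (PTT, reference SBP) calibration/validation experiment.

    Draws ``n`` transit times from Normal(ptt_mean, ptt_sd) ms, builds
    reference systolic pressures SBP = a·PTT + b plus Normal(0,
    noise_sd) mmHg measurement noise, fits the calibration, estimates
    SBP back from PTT and returns the Bland–Altman/AAMI validation.
    """
    rng = np.random.default_rng(seed)
    ptt = rng.normal(ptt_mean, ptt_sd, n)
    sbp = a * ptt + b + rng.normal(0.0, noise_sd, n)
    return pipeline.calibrate_and_validate(ptt, sbp, model_form=model_form)


@dataclass
class ClosureResult:
    """Agreement of recovered vs. embedded transit times, per pair."""

    err_ep_ms: np.ndarray  # measured − embedded, steady-state beats
    err_et_ms: np.ndarray
    triangle_err_ms: np.ndarray  # | |EP−ET| − PT |
    n_beats: int
    n_excluded: int


def ground_truth_closure(
    protocol: SessionProtocol | None = None,
    calib: CalibrationModel | None = None,
) -> ClosureResult:
    """Run the full detection pipeline on a noiseless session and compare
    every recovered pulse-arrival interval with the embedded value.

    The first beat of the session and the first beat of each later
    segment are excluded: the conditioning filters are still settling
    there (session start) or the stepwise BP change of the protocol
    lands inside the detector's rolling window (segment boundaries), so
    those beats measure the protocol's idealized discontinuity rather
    than the pipeline.
    """
    protocol = protocol or SessionProtocol.posture_default()
    calib = calib or CalibrationModel(a=CALIB_SLOPE, b=CALIB_INTERCEPT)
    sess, truth = simulate_session(protocol, NoiseSpec.none(), calib)
    fid = pipeline.detect_fiducials(sess)
    recs = pipeline.beat_records(fid)
    if len(recs) != truth.s_wave_times.size:
        raise RuntimeError(
            f"beat count mismatch: {len(recs)} detected vs "
            f"{truth.s_wave_times.size} embedded"
        )

    edges = np.cumsum([seg.duration for seg in protocol.segments])[:-1]
    first_after_edge = set(np.searchsorted(truth.s_wave_times, edges).tolist())
    excluded = {0} | first_after_edge

    err_ep, err_et, tri = [], [], []
    for i, r in enumerate(recs):
        if i in excluded:
            continue
        if r.ptt_ep is not None:
            err_ep.append(r.ptt_ep - truth.pat_ep[i] * 1000.0)
        if r.ptt_et is not None:
            err_et.append(r.ptt_et - truth.pat_et[i] * 1000.0)
        if r.ptt_ep is not None and r.ptt_et is not None and r.ptt_pt is not None:
            tri.append(abs(abs(r.ptt_ep - r.ptt_et) - r.ptt_pt))
    return ClosureResult(
        err_ep_ms=np.asarray(err_ep),
        err_et_ms=np.asarray(err_et),
        triangle_err_ms=np.asarray(tri),
        n_beats=len(recs),
        n_excluded=len(excluded),
    )
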