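"""PTT→BP calibration and agreement validation.

Blood pressure is calibrated against pulse transit time per subject with
the linear model BP = a·PTT + b fitted by ordinary least squares; a
logarithmic alternative BP = a·ln(PTT) + b is available (both forms
appear in the cuffless-BP literature; the linear form is the default).
Estimated and cuff-measured BP are compared with Bland–Altman statistics
and checked against the AAMI device criteria: |mean difference| ≤ 5 mmHg
and SD of differences ≤ 8 mmHg, boundaries inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AAMI_MEAN_LIMIT_MMHG = 5.0
AAMI_SD_LIMIT_MMHG = 8.0
LOA_FACTOR = 1.96  # limits of agreement: mean ± 1.96·SD


class RankDeficiencyError(ValueError):
    """All PTT values identical: the slope is not identifiable."""


@dataclass
class CalibrationModel:
    """Fitted coefficients of BP = a·PTT + b (or a·ln PTT + b).

    a : mmHg/ms (linear) or mmHg per log-ms (log form)
    b : mmHg intercept
    """

    a: float
    b: float
    model_form: str = "linear"
    target: str = "SBP"
    pair: str = "E-T"
    n_points: int = 0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model_form not in ("linear", "log"):
            raise ValueError(f"unknown model form {self.model_form!r}")


@dataclass
class BlandAltmanResult:
    """Mean, SD and 95% limits of agreement of paired differences."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def fit_calibration(
    ptt,
    bp,
    model_form: str = "linear",
    target: str = "SBP",
    pair: str = "E-T",
) -> CalibrationModel:
    """Ordinary least squares of BP on PTT (or ln PTT for the log form).

    Requires at least two distinct PTT values; the residual standard
    deviation (n−2 denominator when possible) is stored for diagnostics.
    """
    ptt = np.asarray(ptt, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if ptt.shape != bp.shape or ptt.ndim != 1:
        raise ValueError("ptt and bp must be aligned 1-D series")
    if ptt.size < 2:
        raise ValueError("need at least two calibration points")
    if model_form == "log":
        if np.any(ptt <= 0):
            raise ValueError("log form requires positive PTT")
        x = np.log(ptt)
    elif model_form == "linear":
        x = ptt
    else:
        raise ValueError(f"unknown model form {model_form!r}")
    if np.ptp(x) == 0:
        raise RankDeficiencyError("all PTT values identical; slope unidentifiable")
    (a, b), res, *_ = np.polyfit(x, bp, 1, full=True)
    resid = bp - (a * x + b)
    dof = max(ptt.size - 2, 1)
    return CalibrationModel(
        a=float(a),
        b=float(b),
        model_form=model_form,
        target=target,
        pair=pair,
        n_points=int(ptt.size),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def estimate_bp(ptt, model: CalibrationModel):
    """Continuous BP estimate from PTT under a fitted calibration."""
    ptt = np.asarray(ptt, dtype=float)
    if model.model_form == "log":
        if np.any(ptt <= 0):
            raise ValueError("log form requires positive PTT")
        x = np.log(ptt)
    else:
        x = ptt
    out = model.a * x + model.b
    return float(out) if out.ndim == 0 else out


def bland_altman(estimated, measured) -> BlandAltmanResult:
    """Bland–Altman agreement of estimated vs. measured BP.

    Differences are estimated − measured; SD uses the n−1 sample
    convention and the limits of agreement are mean ± 1.96·SD.
    """
    est = np.asarray(estimated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape or est.ndim != 1:
        raise ValueError("series must be aligned 1-D arrays")
    if est.size < 2:
        raise ValueError("need at least two pairs")
    d = est - meas
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_FACTOR * sd,
        loa_high=mean + LOA_FACTOR * sd,
        n=int(d.size),
    )


def aami_check(result: BlandAltmanResult) -> dict:
    """AAMI verdict: pass iff |mean| ≤ 5 mmHg and SD ≤ 8 mmHg (inclusive).

    Returns the verdict and the signed margins to each limit (positive
    margin = inside the limit).
    """
    mean_margin = AAMI_MEAN_LIMIT_MMHG - abs(result.mean_diff)
    sd_margin = AAMI_SD_LIMIT_MMHG - result.sd_diff
    return {
        "pass": bool(mean_margin >= 0 and sd_margin >= 0),
        "mean_diff": result.mean_diff,
        "sd_diff": result.sd_diff,
        "mean_margin_mmHg": float(mean_margin),
        "sd_margin_mmHg": float(sd_margin),
    }
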