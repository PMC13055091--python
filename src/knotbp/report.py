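"""Report bundle: the files a session analysis leaves behind.

A completed run writes, into one directory:

* ``beats.csv``          — per-beat PTT/HR table
* ``calibration.json``   — fitted a, b, n, residual SD, model form
* ``bland_altman.json``  — agreement statistics + AAMI verdict
* ``hemodynamics.csv``   — per-site K / AC / TPR table
* ``run_config.json``    — the configuration that produced it all
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ptt_engine
from .bpcal import BlandAltmanResult, CalibrationModel
from .config import RunConfig
from .pipeline import ValidationBundle


def calibration_dict(m: CalibrationModel) -> dict:
    return {
        "a_mmhg_per_ms": m.a,
        "b_mmhg": m.b,
        "model_form": m.model_form,
        "target": m.target,
        "pair": m.pair,
        "n_points": m.n_points,
        "residual_sd_mmhg": m.residual_sd,
    }


def bland_altman_dict(ba: BlandAltmanResult, aami: dict) -> dict:
    return {
        "mean_diff_mmhg": ba.mean_diff,
        "sd_diff_mmhg": ba.sd_diff,
        "loa_low_mmhg": ba.loa_low,
        "loa_high_mmhg": ba.loa_high,
        "n": ba.n,
        "aami": {
            "verdict": "pass" if aami["pass"] else "fail",
            "mean_margin_mmHg": aami["mean_margin_mmHg"],
            "sd_margin_mmHg": aami["sd_margin_mmHg"],
        },
    }


def hemodynamics_frame(hemo_lists: dict) -> pd.DataFrame:
    """Median per-site K/AC/TPR table from per-cycle parameter lists.

    SV, AC and TPR computed from uncalibrated sensor waveforms are in
    arbitrary pressure units; the ``calibrated`` column records this.
    """
    rows = []
    for site, params in hemo_lists.items():
        if not params:
            continue
        rows.append(
            {
                "site": site,
                "K": float(np.median([p.K for p in params])),
                "AC": float(np.median([p.AC for p in params])),
                "TPR": float(np.median([p.TPR for p in params])),
                "n_cycles": len(params),
                "calibrated": all(p.calibrated for p in params),
            }
        )
    return pd.DataFrame(rows, columns=["site", "K", "AC", "TPR", "n_cycles", "calibrated"])


def write_report(
    outdir,
    records=None,
    validation: ValidationBundle | None = None,
    hemo_lists: dict | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Write whatever parts of the bundle are present; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if records is not None:
        p = out / "beats.csv"
        ptt_engine.records_frame(records).to_csv(p, index=False)
        paths["beats"] = p
    if validation is not None:
        p = out / "calibration.json"
        p.write_text(json.dumps(calibration_dict(validation.model), indent=2) + "\n")
        paths["calibration"] = p
        p = out / "bland_altman.json"
        p.write_text(
            json.dumps(bland_altman_dict(validation.bland_altman, validation.aami), indent=2)
            + "\n"
        )
        paths["bland_altman"] = p
    if hemo_lists is not None:
        p = out / "hemodynamics.csv"
        hemodynamics_frame(hemo_lists).to_csv(p, index=False)
        paths["hemodynamics"] = p
    if config is not None:
        p = out / "run_config.json"
        config.to_json(p)
        paths["config"] = p
    return paths
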