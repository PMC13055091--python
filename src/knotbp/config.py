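"""Run configuration: every tunable of the pipeline in one JSON-round-trip
dataclass, with all defaults embedded so a zero-argument run works.

The paper-stated constants (400 Hz sampling, the 6/3 Hz and 4/1 Hz
cutoffs, the 5/8 mmHg AAMI limits) are defaults here; everything else
(detector parameters, matching window, simulation truth) is a package
default that ``log_unstated_defaults`` records for audit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

from .peakdetect import PeakDetectorParams
from .synthwave import NoiseSpec, ProtocolSegment, SessionProtocol

log = logging.getLogger("knotbp")


@dataclass
class RunConfig:
    sampling_rate: float = 400.0
    sbkp_cutoffs_hz: tuple = (6.0, 3.0)
    ecg_cutoffs_hz: tuple = (4.0, 1.0)
    filter_mode: str = "causal"
    detector_lag_s: float = 0.25
    detector_threshold: float = 3.5
    detector_influence: float = 0.1
    detector_refractory_s: float = 0.25
    max_latency_s: float = 0.6
    model_form: str = "linear"
    aami_mean_limit_mmhg: float = 5.0
    aami_sd_limit_mmhg: float = 8.0
    # simulation ground truth (inverse-calibration slope/intercept)
    sim_calib_a: float = -0.5
    sim_calib_b: float = 180.0
    sim_pair: str = "E-T"
    seed: int = 0

    def detector_params(self) -> PeakDetectorParams:
        return PeakDetectorParams.for_fs(
            self.sampling_rate,
            lag_s=self.detector_lag_s,
            threshold=self.detector_threshold,
            influence=self.detector_influence,
            refractory=self.detector_refractory_s,
        )

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["sbkp_cutoffs_hz"] = list(d["sbkp_cutoffs_hz"])
        d["ecg_cutoffs_hz"] = list(d["ecg_cutoffs_hz"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sbkp_cutoffs_hz", "ecg_cutoffs_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def log_unstated_defaults(self) -> None:
        """Record every default the hardware description leaves open."""
        log.info(
            "detector: lag=%.3fs threshold=%.2f influence=%.2f refractory=%.3fs",
            self.detector_lag_s,
            self.detector_threshold,
            self.detector_influence,
            self.detector_refractory_s,
        )
        log.info("beat matching window: %.3f s", self.max_latency_s)
        log.info("calibration model form: %s (pair %s)", self.model_form, self.sim_pair)


def protocol_from_dict(d: dict) -> SessionProtocol:
    segs = tuple(
        ProtocolSegment(
            label=s["label"],
            duration=float(s["duration"]),
            systolic_bp=float(s["systolic_bp"]),
            diastolic_bp=float(s["diastolic_bp"]),
            heart_rate=float(s["heart_rate"]),
        )
        for s in d["segments"]
    )
    return SessionProtocol(
        segments=segs, sampling_rate=float(d.get("sampling_rate", 400.0))
    )


def protocol_to_dict(p: SessionProtocol) -> dict:
    return {
        "sampling_rate": p.sampling_rate,
        "segments": [
            {
                "label": s.label,
                "duration": s.duration,
                "systolic_bp": s.systolic_bp,
                "diastolic_bp": s.diastolic_bp,
                "heart_rate": s.heart_rate,
            }
            for s in p.segments
        ],
    }


def load_protocol(path) -> SessionProtocol:
    with open(path) as fh:
        return protocol_from_dict(json.load(fh))


def load_noise(path) -> NoiseSpec:
    with open(path) as fh:
        return NoiseSpec(**json.load(fh))
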