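"""Pulse-wave hemodynamics: K, stroke volume, compliance, resistance.

K = (Pm - Pd)/(Ps - Pd) depends only on the normalized cycle shape, so
it is valid on uncalibrated sensor voltages; SV, AC and TPR inherit the
input's pressure units (flagged when uncalibrated).
"""

import numpy as np

from knotbp import pipeline
from knotbp.bpcal import CalibrationModel
from knotbp.report import hemodynamics_frame
from knotbp.synthwave import NoiseSpec, ProtocolSegment, SessionProtocol
from knotbp.synthwave import simulate_session

protocol = SessionProtocol(
    segments=(ProtocolSegment("sitting", 60.0, 120.0, 80.0, 72.0),)
)
session, _ = simulate_session(
    protocol, NoiseSpec.none(), CalibrationModel(a=-0.5, b=180.0)
)
hemo = {
    ch: pipeline.session_hemodynamics(session, channel=ch)
    for ch in ("sbkp", "ppg")
}
print(hemodynamics_frame(hemo).to_string(index=False))
k = np.median([p.K for p in hemo["sbkp"]])
print(f"\nmedian K = {k:.3f}: the fraction of the pulse's span occupied by "
      "its time-average — higher K means a fuller, stiffer-vessel waveform.")
print("AC and TPR above are in arbitrary (sensor) pressure units; with a "
      "calibrated cuff reference they become ml/mmHg and mmHg·s/ml.")
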