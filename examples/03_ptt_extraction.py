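"""Match beats across streams and extract pulse transit times.

Each S wave is paired with the first subsequent pulse foot per channel;
PTT is the absolute difference of the two fiducials in ms. The windowed
summaries report PTT variation (ms/mmHg, how strongly PTT tracks BP)
and variability (ms, beat-to-beat spread).
"""

import numpy as np

from knotbp import pipeline
from knotbp.bpcal import CalibrationModel
from knotbp.ptt_engine import ptt_summaries, records_frame
from knotbp.synthwave import NoiseSpec, SessionProtocol, simulate_session

session, truth = simulate_session(
    SessionProtocol.posture_default(), NoiseSpec(seed=0),
    CalibrationModel(a=-0.5, b=180.0),
)
recs = pipeline.beat_records(pipeline.detect_fiducials(session))
df = records_frame(recs)
print(df.head(5).to_string(index=False))

ok = df["ptt_et_ms"].notna()
ref = pipeline.reference_sbp_at(
    SessionProtocol.posture_default(), df.loc[ok, "s_time_s"].to_numpy()
)
summary = ptt_summaries(df.loc[ok, "ptt_et_ms"].to_numpy(), ref, window=20)
print(f"\nPTT variation:   {summary.variation_mean:.2f} ± "
      f"{summary.variation_sd:.2f} ms/mmHg over {summary.n_windows} windows")
print(f"PTT variability: {summary.variability_mean:.2f} ± "
      f"{summary.variability_sd:.2f} ms")
print("Variation approaches |1/a| of the embedded calibration (2 ms/mmHg) at "
      "the protocol's BP steps, attenuated by detection jitter; variability "
      "reflects that jitter plus measurement noise.")
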