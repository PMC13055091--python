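"""Generator contracts: embedded ground truth, determinism, morphology."""

import numpy as np
import pytest

from knotbp.bpcal import CalibrationModel
from knotbp.hemodynamics import PulseCycle, compute_K
from knotbp.synthwave import (
    AliasingError,
    DegenerateModelError,
    EcgMorphology,
    InfeasibleProtocolError,
    NoiseSpec,
    ProtocolSegment,
    PulseShape,
    SessionProtocol,
    ecg_waveform,
    pulse_waveform,
    simulate_session,
)

FS = 400.0


class TestSimulateSession:
    def test_embedded_ptt_is_inverse_of_linear_calibration(self, true_calib):
        proto = SessionProtocol(
            segments=(ProtocolSegment("x", 30.0, 140.0, 90.0, 60.0),)
        )
        _, truth = simulate_session(proto, NoiseSpec.none(), true_calib)
        # SBP 140 under BP = -0.5·PTT + 180 embeds PTT = 80 ms per beat
        assert np.allclose(truth.ptt_et_ms, 80.0)
        assert np.allclose(
            truth.sbkp_foot_times, truth.s_wave_times + truth.pep_s + 0.080
        )

    def test_identical_seeds_render_bit_identical_sessions(self, true_calib):
        proto = SessionProtocol(
            segments=(ProtocolSegment("x", 20.0, 120.0, 80.0, 72.0),)
        )
        noise = NoiseSpec(seed=99)
        s1, t1 = simulate_session(proto, noise, true_calib, rr_jitter_frac=0.02)
        s2, t2 = simulate_session(proto, noise, true_calib, rr_jitter_frac=0.02)
        for ch in ("ecg", "ppg", "sbkp"):
            assert np.array_equal(s1[ch], s2[ch])
        assert np.array_equal(t1.s_wave_times, t2.s_wave_times)

    def test_posture_protocol_sample_count(self, posture_session):
        sess, _ = posture_session
        # 200 + 150 + 200 s at 400 Hz
        assert sess.n_samples == 550 * 400
        assert sess.duration == pytest.approx(550.0)

    def test_zero_slope_calibration_rejected(self):
        proto = SessionProtocol(
            segments=(ProtocolSegment("x", 20.0, 120.0, 80.0, 72.0),)
        )
        with pytest.raises(DegenerateModelError):
            simulate_session(proto, NoiseSpec.none(), CalibrationModel(a=0.0, b=180.0))

    def test_protocol_implying_negative_ptt_rejected(self, true_calib):
        # SBP 190 under BP = -0.5 PTT + 180 would need PTT = -20 ms
        proto = SessionProtocol(
            segments=(ProtocolSegment("x", 20.0, 190.0, 95.0, 72.0),)
        )
        with pytest.raises(InfeasibleProtocolError):
            simulate_session(proto, NoiseSpec.none(), true_calib)

    def test_noise_energy_matches_spec_within_5pct(self, true_calib):
        proto = SessionProtocol(
            segments=(ProtocolSegment("x", 90.0, 120.0, 80.0, 72.0),)
        )
        noise = NoiseSpec(
            white_sd=0.05,
            baseline_wander_amp=0.08,
            powerline_amp=0.03,
            seed=5,
        )
        noisy, _ = simulate_session(proto, noise, true_calib)
        clean, _ = simulate_session(proto, NoiseSpec.none(), true_calib)
        added = noisy["ecg"] - clean["ecg"]
        expected_var = (
            noise.white_sd**2
            + noise.baseline_wander_amp**2 / 2
            + noise.powerline_amp**2 / 2
        )
        assert np.var(added) == pytest.approx(expected_var, rel=0.05)


class TestEcgWaveform:
    def test_single_beat_has_one_minimum_in_s_window(self):
        m = EcgMorphology()
        y = ecg_waveform([1.0], m, FS, duration=2.0)
        t = np.arange(y.size) / FS
        s_center = 1.0 + m.s_offset
        window = (t > s_center - 0.05) & (t < s_center + 0.05)
        idx = np.flatnonzero(window)
        local = y[idx]
        # exactly one sample-level minimum inside the window
        mins = np.flatnonzero((local[1:-1] < local[:-2]) & (local[1:-1] < local[2:]))
        assert mins.size == 1
        # ... and it is the global minimum of the beat
        assert y.min() == local.min()
        assert abs(t[idx[mins[0] + 1]] - s_center) <= 2.5 / FS

    def test_tachycardia_flag_adds_extra_t_wave_peak(self):
        t = np.arange(int(2 * FS)) / FS
        base = ecg_waveform([1.0], EcgMorphology(), FS, duration=2.0)
        tachy = ecg_waveform([1.0], EcgMorphology(tachycardia=True), FS, duration=2.0)
        sel = (t > 1.1) & (t < 1.5)  # the T-wave region

        def n_peaks(y):
            seg = y[sel]
            return int(
                np.sum((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:]))
            )

        assert n_peaks(base) == 1
        assert n_peaks(tachy) == 2

    def test_zero_amplitude_morphology_is_flat(self):
        m = EcgMorphology(waves=tuple((n, 0.0, o, w) for n, _a, o, w in
                                      EcgMorphology().waves))
        assert np.allclose(ecg_waveform([0.5], m, FS, duration=1.5), 0.0)

    def test_undersampled_kernel_raises_aliasing_error(self):
        with pytest.raises(AliasingError):
            ecg_waveform([1.0], EcgMorphology(), fs=30.0, duration=2.0)

    def test_decreasing_beat_times_rejected(self):
        with pytest.raises(ValueError):
            ecg_waveform([1.0, 0.5], EcgMorphology(), FS)


class TestPulseWaveform:
    def test_cycle_spans_pd_to_ps_within_quantization(self):
        y = pulse_waveform([0.0, 1.0], ps=120.0, pd=80.0, fs=FS, duration=2.0)
        cyc = y[0:400]
        assert cyc.min() == pytest.approx(80.0, abs=1e-9)
        assert cyc.max() == pytest.approx(120.0, abs=0.5)

    def test_zero_dicrotic_amplitude_gives_single_peak(self):
        shape = PulseShape(dicrotic_amp=0.0)
        y = pulse_waveform([0.0], ps=1.0, pd=0.0, shape=shape, fs=FS, duration=0.9)
        peaks = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))
        assert peaks.size == 1

    def test_default_cycle_has_dicrotic_bump(self):
        y = pulse_waveform([0.0], ps=1.0, pd=0.0, fs=FS, duration=0.9)
        peaks = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))
        assert peaks.size == 2  # percussion + dicrotic

    def test_rendered_cycle_K_matches_hemodynamics_module(self):
        """Self-consistency: the generator's K equals compute_K on the
        same samples (no separate bookkeeping of the template's area)."""
        n = 400
        shape = PulseShape()
        u = shape.template(n, FS)
        y = pulse_waveform([0.0, n / FS], ps=120.0, pd=80.0, shape=shape, fs=FS,
                           duration=n / FS)
        k_direct = float(np.trapezoid(u, dx=1 / FS) / ((n - 1) / FS))
        assert compute_K(PulseCycle(samples=y[:n], fs=FS)) == pytest.approx(
            k_direct, abs=1e-12
        )

    def test_overlapping_cycles_rejected(self):
        with pytest.raises(ValueError):
            pulse_waveform([0.0, 0.1], ps=1.0, pd=0.0, fs=FS)

    def test_ps_not_above_pd_rejected(self):
        with pytest.raises(ValueError):
            pulse_waveform([0.0, 1.0], ps=80.0, pd=80.0, fs=FS)


class TestProtocolValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration": 0.0},
            {"heart_rate": 20.0},
            {"heart_rate": 250.0},
            {"systolic_bp": 80.0, "diastolic_bp": 80.0},
            {"diastolic_bp": -1.0},
        ],
    )
    def test_invalid_segments_rejected(self, kwargs):
        base = dict(
            label="x", duration=10.0, systolic_bp=120.0, diastolic_bp=80.0,
            heart_rate=70.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            ProtocolSegment(**base)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            SessionProtocol(segments=())

    def test_negative_noise_amplitude_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(white_sd=-0.1)
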