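"""Triboelectric output model and bench-characterization statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knotbp.tribo import (
    NO_RESOLUTION,
    TriboMaterial,
    TriboPairConfig,
    enhancement_percent,
    hysteresis_error,
    knot_areas,
    open_circuit_voltage,
    power_density,
    resolution_estimate,
    sensitivity_fit,
    stored_energy,
    tribo_charge,
    voltage_ratio,
)

PET = TriboMaterial("PET", work_function=4.25, thickness=100e-6)
PTFE = TriboMaterial("PTFE", work_function=5.75, thickness=50e-6)


def make_config(effective_mm2=675.0, apparent_mm2=675.0, **kw):
    defaults = dict(
        donor=PET,
        acceptor=PTFE,
        effective_area=effective_mm2 * 1e-6,
        apparent_area=apparent_mm2 * 1e-6,
        surface_charge_density=1e-5,
        gap=1e-3,
        permittivity=8.854e-12,
    )
    defaults.update(kw)
    return TriboPairConfig(**defaults)


class TestTriboCharge:
    def test_equal_work_functions_no_charge(self):
        same = TriboMaterial("X", 5.0, 1e-4)
        cfg = make_config(donor=same, acceptor=same)
        assert tribo_charge(cfg) == 0.0

    def test_proportional_to_effective_area(self):
        q1 = tribo_charge(make_config(effective_mm2=675.0))
        q2 = tribo_charge(make_config(effective_mm2=1350.0))
        assert q2 == pytest.approx(2.0 * q1)
        q3 = tribo_charge(make_config(effective_mm2=900.0))
        assert q3 / q1 == pytest.approx(4.0 / 3.0)

    def test_sign_follows_donor_acceptor_ordering(self):
        assert tribo_charge(make_config()) < 0  # PET donor below PTFE acceptor


class TestOpenCircuitVoltage:
    def test_zero_charge_limit_is_sigma_d_over_epsilon(self):
        same = TriboMaterial("X", 5.0, 1e-4)
        cfg = make_config(donor=same, acceptor=same)
        assert open_circuit_voltage(cfg) == pytest.approx(
            cfg.surface_charge_density * cfg.gap / cfg.permittivity
        )

    def test_zero_gap_limit(self):
        cfg = make_config(gap=0.0)
        expected = -tribo_charge(cfg) * cfg.layer_thickness / (
            cfg.apparent_area * cfg.permittivity
        )
        assert open_circuit_voltage(cfg) == pytest.approx(expected)

    def test_generic_config_matches_two_term_hand_evaluation(self):
        cfg = make_config(effective_mm2=900.0, apparent_mm2=600.0)
        qt = cfg.effective_area * (
            cfg.donor.work_function - cfg.acceptor.work_function
        )
        by_hand = (
            -qt / (cfg.apparent_area * cfg.permittivity)
            * (cfg.donor.thickness + cfg.acceptor.thickness + cfg.gap)
            + cfg.surface_charge_density * cfg.gap / cfg.permittivity
        )
        assert open_circuit_voltage(cfg) == pytest.approx(by_hand, rel=1e-12)


class TestVoltageRatio:
    def test_box_knot_over_plane_is_effective_area_ratio(self):
        box = make_config(effective_mm2=900.0, apparent_mm2=675.0)
        plane = make_config(effective_mm2=675.0, apparent_mm2=675.0)
        assert voltage_ratio(box, plane) == pytest.approx(4.0 / 3.0)

    def test_equal_configs_give_unity(self):
        assert voltage_ratio(make_config(), make_config()) == pytest.approx(1.0)

    def test_mismatched_gap_violates_contract(self):
        with pytest.raises(ValueError):
            voltage_ratio(make_config(gap=1e-3), make_config(gap=2e-3))

    @settings(max_examples=30, deadline=None)
    @given(
        ae_b=st.floats(1e-4, 1e-2),
        ae_p=st.floats(1e-4, 1e-2),
        sigma=st.floats(0.0, 1e-4),
        gap=st.floats(0.0, 1e-2),
    )
    def test_reduces_to_area_ratio_for_shared_parameters(self, ae_b, ae_p, sigma, gap):
        shared = dict(
            donor=PET,
            acceptor=PTFE,
            apparent_area=min(ae_b, ae_p),
            surface_charge_density=sigma,
            gap=gap,
            permittivity=8.854e-12,
        )
        box = TriboPairConfig(effective_area=ae_b, **shared)
        plane = TriboPairConfig(effective_area=ae_p, **shared)
        assert voltage_ratio(box, plane) == pytest.approx(ae_b / ae_p, rel=1e-9)


class TestKnotAreas:
    def test_three_knottings_of_15mm_top_plane(self):
        apparent, effective = knot_areas(15.0, 3, second_layer_contact=False)
        assert apparent == pytest.approx(675.0)
        assert effective == pytest.approx(675.0)

    def test_second_layer_contact_adds_one_plane(self):
        _, effective = knot_areas(15.0, 3, second_layer_contact=True)
        assert effective == pytest.approx(900.0)

    def test_single_layer(self):
        assert knot_areas(10.0, 1, False) == (100.0, 100.0)


class TestEnergyAndPower:
    def test_stored_energy_forward_checks(self):
        # 4.7 nF charged to 12 V stores 338.4 nJ; at 10 V, 235 nJ
        assert stored_energy(4.7e-9, 12.0) == pytest.approx(338.4e-9)
        assert stored_energy(4.7e-9, 10.0) == pytest.approx(235.0e-9)
        ratio = stored_energy(4.7e-9, 12.0) / stored_energy(4.7e-9, 10.0)
        assert ratio - 1.0 == pytest.approx(0.44)
        assert stored_energy(4.7e-9, 0.0) == 0.0

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(1e-12, 1e-3), u=st.floats(0.0, 1e3), k=st.floats(0.0, 10.0))
    def test_stored_energy_quadratic_homogeneity(self, c, u, k):
        assert stored_energy(c, k * u) == pytest.approx(
            k**2 * stored_energy(c, u), rel=1e-9, abs=1e-300
        )

    def test_power_density_peak_and_scaling(self):
        assert power_density([1.0], 1.0, 1.0) == pytest.approx(1.0)
        assert power_density([0.5, 2.0, 1.0], 1.0, 1.0) == pytest.approx(4.0)
        assert power_density([2.0], 1.0, 1.0) == pytest.approx(
            4.0 * power_density([1.0], 1.0, 1.0)
        )

    def test_nonpositive_load_rejected(self):
        with pytest.raises(ValueError):
            power_density([1.0], 0.0, 1.0)


class TestSensitivityFit:
    def test_exact_line_recovers_slope_in_mv_per_pa(self):
        p_kpa = np.linspace(0.0, 0.4, 9)
        voc = 0.01 * (p_kpa * 1000.0)  # 0.01 V/Pa = 10 mV/Pa
        assert sensitivity_fit(voc, p_kpa) == pytest.approx(10.0)

    def test_points_above_linear_range_are_ignored(self):
        p_kpa = np.array([0.1, 0.2, 0.3, 0.4, 2.0])
        voc = 0.01 * (p_kpa * 1000.0)
        voc[-1] = 0.0  # saturated point must not bias the slope
        assert sensitivity_fit(voc, p_kpa, linear_max_kpa=0.44) == pytest.approx(10.0)

    def test_noisy_slope_recovered_within_ols_error(self):
        rng = np.random.default_rng(11)
        p_kpa = np.linspace(0.02, 0.44, 40)
        slope_mv_pa = 38.17
        voc = slope_mv_pa * 1e-3 * (p_kpa * 1000.0) + rng.normal(0, 0.2, 40)
        assert sensitivity_fit(voc, p_kpa) == pytest.approx(slope_mv_pa, rel=0.05)

    def test_zero_pressure_variance_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_fit([1.0, 2.0], [0.1, 0.1])


class TestResolutionEstimate:
    def test_well_separated_grid_resolves_at_its_spacing(self):
        p = np.arange(0.0, 0.05, 0.005)
        reps = [[1.0 * i, 1.0 * i + 1e-6] for i in range(p.size)]
        res, ineffective = resolution_estimate(p, reps)
        assert res == pytest.approx(0.005)
        assert ineffective == []

    def test_identical_voltages_have_no_resolution(self):
        p = np.array([0.0, 0.01, 0.02])
        reps = [[1.0, 1.0]] * 3
        res, ineffective = resolution_estimate(p, reps)
        assert res == NO_RESOLUTION
        assert ineffective == [0, 1]

    def test_constructed_grid_resolves_at_6_pa(self):
        """Noise tuned so only the 0.006 kPa-spaced steps separate."""
        rng = np.random.default_rng(3)
        p = np.array([0.000, 0.003, 0.009])  # spacings 0.003 and 0.006 kPa
        gain = 1000.0  # V per kPa
        noise_sd = 2.0  # separates 6 V gaps (k=2) but not 3 V gaps
        reps = [gain * pi + rng.normal(0, noise_sd, 12) for pi in p]
        res, ineffective = resolution_estimate(p, reps)
        assert res == pytest.approx(0.006)
        assert 0 in ineffective

    def test_single_step_rejected(self):
        with pytest.raises(ValueError):
            resolution_estimate([0.1], [[1.0, 1.1]])


class TestHysteresisError:
    def test_identical_curves_zero_error(self):
        curve = [(p, 2.0 * p) for p in np.linspace(0, 1, 11)]
        assert hysteresis_error(curve, curve) == pytest.approx(0.0)

    def test_constant_offset_on_full_scale(self):
        loading = [(p, 10.0 * p) for p in np.linspace(0, 1, 11)]
        unloading = [(p, 10.0 * p + 0.35) for p in np.linspace(0, 1, 11)]
        # full scale = 10 V, offset 0.35 V -> 3.5 %
        assert hysteresis_error(loading, unloading) == pytest.approx(3.5)

    def test_matches_dense_grid_brute_force(self):
        rng = np.random.default_rng(8)
        p = np.linspace(0.0, 1.0, 21)
        vl = 10.0 * p**1.2
        vu = 10.0 * p**0.8
        loading = list(zip(p, vl))
        unloading = list(zip(p, vu))
        dense = np.linspace(0.0, 1.0, 20001)
        brute = 100.0 * np.max(
            np.abs(np.interp(dense, p, vl) - np.interp(dense, p, vu))
        ) / vl.max()
        assert hysteresis_error(loading, unloading) == pytest.approx(brute, rel=1e-3)
        del rng

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_error([(0.0, 0.0), (1.0, 1.0)], [(2.0, 0.0), (3.0, 1.0)])


class TestEnhancementPercent:
    def test_both_baseline_conventions(self):
        d = enhancement_percent(78.2, 58.4)
        assert d["vs_control"] == pytest.approx(33.9, abs=0.05)
        assert d["vs_test"] == pytest.approx(25.3, abs=0.05)
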