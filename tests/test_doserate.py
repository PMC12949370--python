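"""Delivery-physics arithmetic: histories, dose rates, pulses, dwell maps."""

import numpy as np
import pytest

from radioser.doserate import (
    DwellPlan,
    GridSpec,
    PulseSpec,
    SourceSpec,
    average_dose_rate,
    distance_for_dose_rate_factor,
    dose_per_pulse,
    dwell_dose_rate,
    map_summary,
    particle_histories,
    point_source_rate,
    pulse_instantaneous_dose_rate,
    simulate_dwell_timeline,
)
from radioser.simulate import generate_dwell_plan

HOT = SourceSpec(air_kerma_strength=37.95)
COLD = SourceSpec(air_kerma_strength=18.97)


class TestParticleHistories:
    def test_worked_conversion_chain(self):
        # 37.95 mGy*m^2/h -> 37950 cGy*cm^2/h -> /4.037 = 9401 mCi -> 9.401 Ci
        expected = 37950.0 / 4.037 / 1000.0 * 3.7e10
        assert particle_histories(HOT, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.478e11, rel=1e-3)

    def test_zero_time_zero_histories(self):
        assert particle_histories(HOT, 0.0) == 0.0

    def test_linearity_in_time_and_strength(self):
        assert particle_histories(HOT, 20.0) == pytest.approx(
            2 * particle_histories(HOT, 10.0), rel=1e-12
        )
        double = SourceSpec(air_kerma_strength=2 * 37.95)
        assert particle_histories(double, 5.0) == pytest.approx(
            2 * particle_histories(HOT, 5.0), rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            particle_histories(HOT, -1.0)


class TestDoseRates:
    def test_dwell_rate_hand_value(self):
        # 2 Gy over 109.09 s ~ 1.1 Gy/min average delivery
        rate = dwell_dose_rate(2.0, 109.09)
        assert rate == pytest.approx(0.018334, abs=1e-6)
        assert rate * 60 == pytest.approx(1.100, abs=1e-3)

    def test_dwell_rate_inverse_in_time(self):
        assert dwell_dose_rate(2.0, 218.18) == pytest.approx(
            dwell_dose_rate(2.0, 109.09) / 2, rel=1e-12
        )

    @pytest.mark.parametrize(
        "dose, time, expected",
        [(2.0, 109.09, 1.1), (2.0, 218.18, 0.55), (0.0, 100.0, 0.0)],
    )
    def test_average_rate(self, dose, time, expected):
        assert average_dose_rate(dose, time) == pytest.approx(expected, abs=1e-3)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            dwell_dose_rate(2.0, 0.0)
        with pytest.raises(ValueError):
            average_dose_rate(2.0, 0.0)


class TestPulseStructure:
    def test_default_dose_per_pulse_from_calibration(self):
        # 200 cGy / 220 MU * 0.08 MU/pulse
        assert dose_per_pulse(PulseSpec()) == pytest.approx(0.0727, abs=1e-4)

    def test_dose_per_pulse_linearity(self):
        base = dose_per_pulse(PulseSpec())
        assert dose_per_pulse(PulseSpec(mu_per_pulse=0.16)) == pytest.approx(2 * base)
        assert dose_per_pulse(PulseSpec(mu_per_pulse=0.03, calibration=1.0)) == pytest.approx(0.03)

    @pytest.mark.parametrize(
        "dpp_cgy, width, expected",
        [(0.072, 4e-6, 180.0), (0.036, 4e-6, 90.0), (0.072, 8e-6, 90.0)],
    )
    def test_instantaneous_rate(self, dpp_cgy, width, expected):
        assert pulse_instantaneous_dose_rate(dpp_cgy, width) == pytest.approx(expected)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            pulse_instantaneous_dose_rate(0.072, 0.0)


class TestDistanceMatching:
    def test_half_rate_from_91cm(self):
        d = distance_for_dose_rate_factor(91.0, 0.5)
        assert d == pytest.approx(128.69, abs=0.01)
        assert round(d) == 129

    def test_identity_and_quarter(self):
        assert distance_for_dose_rate_factor(91.0, 1.0) == pytest.approx(91.0)
        assert distance_for_dose_rate_factor(91.0, 0.25) == pytest.approx(182.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            distance_for_dose_rate_factor(91.0, 0.0)


class TestPointSource:
    def test_reference_rate_at_1cm(self):
        # 37950 U * 1.109 cGy/h/U = 42087 cGy/h = 7.01 Gy/min
        assert point_source_rate(HOT, 1.0) == pytest.approx(7.01, abs=0.01)
        assert point_source_rate(HOT, 2.0) == pytest.approx(7.01 / 4, abs=0.01)

    def test_inverse_square_invariant(self):
        r = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        prod = point_source_rate(HOT, r) * r * r
        np.testing.assert_allclose(prod, prod[0], rtol=1e-12)

    def test_strength_linearity(self):
        np.testing.assert_allclose(
            point_source_rate(HOT, 3.0) / point_source_rate(COLD, 3.0),
            37.95 / 18.97,
            rtol=1e-12,
        )

    def test_singularity_rejected(self):
        with pytest.raises(ZeroDivisionError):
            point_source_rate(HOT, 0.0)


class TestDwellMap:
    def test_single_dwell_peaks_at_center_and_decays(self):
        plan = generate_dwell_plan(1, time_per_dwell_s=30.0, channel_height_cm=1.5)
        m = simulate_dwell_timeline(plan, HOT, GridSpec(3.5, 50))
        peak = np.unravel_index(np.argmax(m.max_rate), m.max_rate.shape)
        center = (24, 24)  # voxel centers nearest origin for even bins
        assert peak in {center, (24, 25), (25, 24), (25, 25)}
        mid = m.max_rate[:, 24]
        assert np.all(np.diff(mid[25:]) < 0) and np.all(np.diff(mid[:24]) > 0)

    def test_split_dwell_equals_single_long_dwell(self):
        one = DwellPlan(positions=[[0, 0, 1.5]], times=[60.0])
        two = DwellPlan(positions=[[0, 0, 1.5], [0, 0, 1.5]], times=[30.0, 30.0])
        m1 = simulate_dwell_timeline(one, HOT)
        m2 = simulate_dwell_timeline(two, HOT)
        np.testing.assert_allclose(m1.total_dose, m2.total_dose, rtol=1e-12)
        np.testing.assert_allclose(m1.max_rate, m2.max_rate, rtol=1e-12)

    def test_hot_cold_ratio_uniform_across_map(self):
        plan = generate_dwell_plan(5, step_cm=0.5, time_per_dwell_s=10.0)
        mh = simulate_dwell_timeline(plan, HOT)
        mc = simulate_dwell_timeline(plan, COLD)
        np.testing.assert_allclose(mh.max_rate / mc.max_rate, 37.95 / 18.97, rtol=1e-12)

    def test_total_dose_is_time_integral_of_timeline(self):
        plan = generate_dwell_plan(4, step_cm=0.7, time_per_dwell_s=12.0)
        m = simulate_dwell_timeline(plan, HOT)
        tl = m.timeline(10, 30)
        integral = float((tl.dose_rate_gy_min / 60.0 * tl.dwell_time_s).sum())
        assert integral == pytest.approx(m.total_dose[10, 30], rel=1e-12)

    def test_max_at_least_average_everywhere(self):
        plan = generate_dwell_plan(6, step_cm=0.4, time_per_dwell_s=8.0)
        m = simulate_dwell_timeline(plan, HOT)
        assert np.all(m.max_rate >= m.avg_rate - 1e-15)

    def test_coincident_dwell_rejected(self):
        grid = GridSpec(3.5, 50)
        c = grid.centers()
        plan = DwellPlan(positions=[[c[25], c[25], 0.0]], times=[10.0])
        with pytest.raises(ZeroDivisionError):
            simulate_dwell_timeline(plan, HOT, grid)

    def test_summary_fields(self):
        plan = generate_dwell_plan(3)
        s = map_summary(simulate_dwell_timeline(plan, HOT))
        assert s["max_rate_max_gy_min"] >= s["max_rate_mean_gy_min"] >= s["max_rate_min_gy_min"]
        assert s["total_time_s"] == pytest.approx(30.0)
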