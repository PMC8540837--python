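"""Closed-bottle CH4 mass balance, Henry partitioning, and rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peatmox import (
    BottleSpec,
    CellStandard,
    GasTimeSeries,
    HenryParams,
    SoilContext,
    ValidationError,
    apply_sampling_corrections,
    cells_from_od,
    dissolved_ch4,
    equivalent_mixing_ratio,
    fit_first_order,
    headspace_after_injection,
    headspace_moles,
    rate_at_concentration,
    rate_per_cell,
    rate_per_dry_weight,
    total_ch4_mass,
)
from peatmox.gas_kinetics import R_GAS
from peatmox.simulate import gen_gas_series

CULTURE_BOTTLE = BottleSpec(total_volume=125.0, liquid_volume=21.6, temperature=8.0)


class TestDissolvedCH4:
    @pytest.mark.parametrize(
        "ppm, temp_c, expected_um",
        [
            (1000, 8, 2.0),    # 0.1% headspace at 8 C
            (1000, 15, 1.7),   # 0.1% at 15 C
            (10000, 8, 20.0),  # 1% at 8 C
            (10000, 15, 17.0), # 1% at 15 C
        ],
    )
    def test_reproduces_reported_dissolved_equivalents(self, ppm, temp_c, expected_um):
        assert dissolved_ch4(ppm, temp_c) == pytest.approx(expected_um, rel=0.10)

    def test_zero_in_zero_out(self):
        assert dissolved_ch4(0.0, 8.0) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.0, max_value=30.0), st.floats(min_value=0.1, max_value=10.0))
    def test_strictly_decreasing_in_temperature(self, temp_c, dt):
        assert dissolved_ch4(1000, temp_c) > dissolved_ch4(1000, temp_c + dt)

    def test_linear_in_mixing_ratio(self):
        assert dissolved_ch4(2000, 8) == pytest.approx(2 * dissolved_ch4(1000, 8))

    def test_rejects_negative_ratio_and_nonphysical_temperature(self):
        with pytest.raises(ValidationError):
            dissolved_ch4(-1.0, 8.0)
        with pytest.raises(ValidationError):
            dissolved_ch4(100.0, -300.0)

    def test_custom_henry_params_validated(self):
        with pytest.raises(ValidationError):
            HenryParams(kh_ref=-1.0)


class TestInjectionArithmetic:
    @pytest.mark.parametrize(
        "injected_ml, expected_ppm",
        [(0.2, 1900), (0.6, 5400), (1.5, 13000), (3.0, 25000)],
    )
    def test_reproduces_reported_headspace_series(self, injected_ml, expected_ppm):
        ppm = headspace_after_injection(CULTURE_BOTTLE, injected_ml, 0.95)
        assert ppm == pytest.approx(expected_ppm, rel=0.10)

    def test_zero_injection(self):
        assert headspace_after_injection(CULTURE_BOTTLE, 0.0) == 0.0

    def test_negative_injection_rejected(self):
        with pytest.raises(ValidationError):
            headspace_after_injection(CULTURE_BOTTLE, -0.1)

    def test_round_trip_matches_direct_ideal_gas_moles(self):
        # moles in the expanded gas phase equal PV=nRT on the injected CH4
        injected, purity = 0.6, 0.95
        ppm = headspace_after_injection(CULTURE_BOTTLE, injected, purity)
        expanded = BottleSpec(
            total_volume=CULTURE_BOTTLE.total_volume + injected,
            liquid_volume=CULTURE_BOTTLE.liquid_volume,
            temperature=CULTURE_BOTTLE.temperature,
        )
        direct = 1e6 * 1.0 * (injected * purity / 1000.0) / (R_GAS * expanded.temperature_k)
        assert headspace_moles(expanded, ppm) == pytest.approx(direct, rel=1e-10)


class TestHeadspaceMoles:
    def test_hand_evaluated_ideal_gas_case(self):
        bottle = BottleSpec(total_volume=46.0, liquid_volume=0.0, temperature=8.0)
        assert headspace_moles(bottle, 10_000) == pytest.approx(19.9, rel=5e-3)

    def test_zero_and_linearity(self):
        bottle = BottleSpec(50.0, 0.0, 8.0)
        assert headspace_moles(bottle, 0.0) == 0.0
        assert headspace_moles(bottle, 2000) == pytest.approx(2 * headspace_moles(bottle, 1000))


class TestTotalMass:
    def test_no_liquid_equals_headspace_moles(self):
        bottle = BottleSpec(50.0, 0.0, 8.0)
        assert total_ch4_mass(bottle, 5000) == headspace_moles(bottle, 5000)

    def test_sum_of_independent_phase_terms(self):
        ppm = 1900.0
        expected = headspace_moles(CULTURE_BOTTLE, ppm) + dissolved_ch4(
            ppm, 8.0
        ) * 21.6 / 1000.0
        assert total_ch4_mass(CULTURE_BOTTLE, ppm) == pytest.approx(expected, rel=1e-12)

    def test_increases_with_liquid_volume_at_fixed_headspace(self):
        headspace = 103.4
        masses = [
            total_ch4_mass(BottleSpec(headspace + lv, lv, 8.0), 1900.0)
            for lv in (0.0, 10.0, 21.6)
        ]
        assert masses[0] < masses[1] < masses[2]


class TestSamplingCorrections:
    def test_zero_sampling_is_identity(self):
        series, _ = gen_gas_series(0.05, 10_000, [0, 5, 10, 20], seed=1)
        corr = apply_sampling_corrections(series)
        np.testing.assert_allclose(corr.corrected_mass, corr.measured_mass)
        assert np.all(corr.removed_cum == 0)

    def test_gas_removal_proportional_to_sampled_fraction(self):
        bottle = BottleSpec(100.0, 0.0, 8.0)
        series = GasTimeSeries(
            times=np.array([0.0, 1.0]),
            mixing_ratios=np.array([1000.0, 1000.0]),
            bottle=bottle,
            gas_sample_volume=0.5,
        )
        corr = apply_sampling_corrections(series)
        assert corr.removed_cum[1] == pytest.approx(0.005 * corr.measured_mass[0])

    def test_sampling_only_series_shows_zero_oxidation(self):
        bottle = BottleSpec(125.0, 21.6, 8.0)
        series, _ = gen_gas_series(
            0.0, 10_000, [0, 2, 4, 6, 8], bottle=bottle,
            gas_sample_volume=0.5, liquid_sample_volume=0.34, sampling_losses=True,
        )
        corr = apply_sampling_corrections(series)
        np.testing.assert_allclose(corr.oxidized_cum, 0.0, atol=1e-9 * corr.initial_mass)

    def test_mass_conservation(self):
        bottle = BottleSpec(125.0, 21.6, 15.0)
        series, _ = gen_gas_series(
            0.08, 25_000, [0, 2, 4, 8], bottle=bottle,
            gas_sample_volume=0.5, liquid_sample_volume=0.34, sampling_losses=True,
        )
        corr = apply_sampling_corrections(series)
        balance = corr.oxidized_cum + corr.removed_cum + corr.measured_mass
        np.testing.assert_allclose(balance, corr.initial_mass, rtol=1e-9)

    def test_oversized_sample_volume_rejected(self):
        bottle = BottleSpec(50.0, 0.0, 8.0)
        series = GasTimeSeries(
            times=np.array([0.0, 1.0]),
            mixing_ratios=np.array([100.0, 90.0]),
            bottle=bottle,
            gas_sample_volume=60.0,
        )
        with pytest.raises(ValidationError):
            apply_sampling_corrections(series)


class TestFirstOrderFit:
    def test_exact_exponential_recovered(self):
        series, _ = gen_gas_series(0.1, 1000.0, [0, 10, 20, 30], noise_sd=0.0)
        fit = fit_first_order(series)
        assert fit.k == pytest.approx(0.1, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 4

    @pytest.mark.parametrize("k", [1e-3, 1e-2, 0.1, 1.0])
    def test_noiseless_recovery_across_rate_magnitudes(self, k):
        series, _ = gen_gas_series(k, 5000.0, np.linspace(0, 20, 5), noise_sd=0.0)
        assert fit_first_order(series).k == pytest.approx(k, rel=1e-9)

    def test_constant_series_reports_degenerate_zero(self):
        series, _ = gen_gas_series(0.0, 1000.0, [0, 10, 20], noise_sd=0.0)
        fit = fit_first_order(series)
        assert fit.k == 0.0
        assert fit.r_squared == 0.0
        assert fit.degenerate

    def test_nonpositive_ratios_and_short_series_rejected(self):
        bottle = BottleSpec(50.0)
        with pytest.raises(ValidationError):
            fit_first_order(
                GasTimeSeries(np.array([0.0, 1.0]), np.array([0.0, 10.0]), bottle)
            )
        with pytest.raises(ValidationError):
            fit_first_order(GasTimeSeries(np.array([0.0]), np.array([10.0]), bottle))

    def test_noisy_parameter_recovery_and_coverage(self):
        # 200 seeded series at 5% multiplicative noise, k = 0.05 h-1
        k_true, errors = 0.05, []
        for seed in range(200):
            series, _ = gen_gas_series(
                k_true, 10_000, [0, 10, 20, 30, 40], noise_sd=0.05, seed=seed
            )
            errors.append(abs(fit_first_order(series).k - k_true) / k_true)
        assert np.median(errors) < 0.05


class TestRateNormalizations:
    def test_rate_at_concentration(self):
        assert rate_at_concentration(0.1, 20.0) == pytest.approx(2.0)
        assert rate_at_concentration(0.1, 0.0) == 0.0

    def test_equal_dissolved_equivalent_ratio(self):
        # 1000 ppm at 8 C needs ~16% more headspace CH4 at 15 C
        equiv = equivalent_mixing_ratio(1000.0, 8.0, 15.0)
        assert equiv / 1000.0 == pytest.approx(1.163, abs=0.01)

    def test_dry_weight_normalization(self):
        soil = SoilContext(fresh_mass=4.0, water_fraction=0.8)
        assert soil.dry_mass == pytest.approx(0.8)
        assert rate_per_dry_weight(1.0, soil) == pytest.approx(16.04 * 24 / 0.8)
        half = SoilContext(fresh_mass=2.0, water_fraction=0.8)
        assert rate_per_dry_weight(1.0, half) == pytest.approx(2 * rate_per_dry_weight(1.0, soil))

    def test_per_cell_normalization(self):
        rate = rate_per_cell(0.5, 5e7, 21.6)
        assert rate == pytest.approx(0.5 / 1.08e9 * 1e8, rel=1e-12)
        assert rate_per_cell(0.5, 1e8, 21.6) == pytest.approx(rate / 2)
        assert rate_per_cell(0.0, 5e7, 21.6) == 0.0
        with pytest.raises(ValidationError):
            rate_per_cell(0.5, 0.0, 21.6)


class TestCellStandard:
    def test_collinear_standard_recovered_exactly(self):
        od = np.linspace(0.01, 0.7, 8)
        counts = 1e8 * od + 5e5
        std = CellStandard(od, counts)
        assert std.r_squared == pytest.approx(1.0)
        for o, c in zip(od, counts):
            assert cells_from_od(o, std) == pytest.approx(c)

    def test_noisy_standard_emulating_culture_range(self):
        # 14 points spanning OD 0.0085-0.7295 and counts 6.1e5-7.266e7
        rng = np.random.default_rng(42)
        od = np.linspace(0.0085, 0.7295, 14)
        slope = (7.266e7 - 6.1e5) / (0.7295 - 0.0085)
        counts = slope * (od - 0.0085) + 6.1e5
        noisy = counts * (1 + rng.normal(0, 0.1, size=14))
        std = CellStandard(od, noisy)
        assert 0 < std.r_squared <= 1.0
        resid_band = np.abs(noisy - (std.slope * od + std.intercept)).max()
        for o, c in zip(od, noisy):
            assert abs(cells_from_od(o, std) - c) <= resid_band + 1e-6

    def test_below_intercept_root_clamped_to_zero(self):
        std = CellStandard([0.1, 0.2, 0.3], [1e6, 2e6, 3e6])
        assert std.intercept < 0
        assert cells_from_od(0.0, std) == 0.0

    def test_single_point_standard_rejected(self):
        with pytest.raises(ValidationError):
            CellStandard([0.1], [1e6])
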