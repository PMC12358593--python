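"""Differential thermodynamics: Gibbs energy, isosteric heat, entropy,
spreading pressure and enthalpy-entropy compensation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from capsorb import (
    DegenerateDataError,
    DomainError,
    GAS_CONSTANT,
    IsothermParams,
    RangeError,
    ThermoPoint,
    ValidationError,
    compensation_fit,
    default_emc_grid,
    gibbs_free_energy,
    harmonic_mean_temperature,
    isosteric_analysis,
    spreading_pressure,
)
from capsorb.synthetic import simulate_compensation_series

from conftest import GAB_32, SMITH_25, SMITH_37

TEMPS = [298.15, 305.15, 310.15]


class TestGibbs:
    def test_zero_at_saturation(self):
        assert gibbs_free_energy(298.15, 1.0) == 0.0

    def test_frozen_hand_value(self):
        # 8.314 * 298.15 * ln 2, computed at high precision beforehand
        assert gibbs_free_energy(298.15, 0.5) == pytest.approx(
            1718.1864702831411, rel=1e-12
        )

    @pytest.mark.parametrize("aw", [0.0, -0.1, 1.1])
    def test_domain_errors(self, aw):
        with pytest.raises(DomainError):
            gibbs_free_energy(298.15, aw)

    def test_strictly_decreasing_in_aw_and_vanishing_at_one(self):
        grid = np.linspace(0.05, 1.0, 100)
        dg = [gibbs_free_energy(298.15, a) for a in grid]
        assert all(x > y for x, y in zip(dg, dg[1:]))
        assert dg[-1] == 0.0
        assert gibbs_free_energy(298.15, 1.0 - 1e-12) < 1e-6


def _constant_aw_fits(aw):
    """Two Smith isotherms chosen so a given EMC inverts to the same aw at
    both temperatures (zero Clausius-Clapeyron slope)."""
    return {
        298.15: IsothermParams("Smith", {"a": 1.0, "b": -10.0}),
        310.15: IsothermParams("Smith", {"a": 1.0, "b": -10.0}),
    }


class TestIsostericAnalysis:
    def test_identical_aw_across_temperatures_gives_zero_heat(self):
        fits = _constant_aw_fits(0.6)
        emc = 1.0 - 10.0 * math.log1p(-0.6)
        (pt,) = isosteric_analysis(fits, [emc])
        assert pt.qst == pytest.approx(0.0, abs=1e-7)
        assert pt.dS == pytest.approx(GAS_CONSTANT * math.log(0.6), rel=1e-9)
        assert pt.fit_r2 == 1.0

    def test_exact_recovery_on_constructed_data(self):
        # aw(T) built from the Clausius-Clapeyron identity with known q, s;
        # the regression must return them exactly (oracle by construction)
        q, s = 5000.0, 10.0
        fits = {}
        for T in TEMPS:
            aw = math.exp(-q / (GAS_CONSTANT * T) + s / GAS_CONSTANT)
            # Smith isotherm passing through (aw, emc=7) with slope -5
            a = 7.0 + 5.0 * math.log1p(-aw)
            fits[T] = IsothermParams("Smith", {"a": a, "b": -5.0})
        (pt,) = isosteric_analysis(fits, [7.0])
        assert pt.qst == pytest.approx(q, rel=1e-6)
        assert pt.dS == pytest.approx(s, rel=1e-6)

    def test_two_temperatures_fit_r2_is_one(self):
        fits = {298.15: SMITH_25, 310.15: SMITH_37}
        grid = default_emc_grid(fits, n=5)
        for pt in isosteric_analysis(fits, grid):
            assert pt.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_emc_raises_range_error(self):
        fits = {298.15: SMITH_25, 310.15: SMITH_37}
        with pytest.raises(RangeError):
            isosteric_analysis(fits, [1e6])

    def test_single_temperature_rejected(self):
        with pytest.raises(ValidationError):
            isosteric_analysis({298.15: SMITH_25}, [5.0])

    def test_default_grid_spans_common_range(self):
        # docs-scale GAB at 32 degC: the published x0 lives on an EMC scale
        # that cannot overlap the Smith curves (scale anomaly kept as-is)
        gab_coherent = IsothermParams("GAB", {"k": 0.89, "c": 13.17, "x0": 4.0})
        fits = {298.15: SMITH_25, 305.15: gab_coherent, 310.15: SMITH_37}
        grid = default_emc_grid(fits, n=20)
        assert len(grid) == 20
        assert np.all(np.diff(grid) > 0)
        # every grid point inverts everywhere (no RangeError)
        pts = isosteric_analysis(fits, grid)
        assert len(pts) == 20


class TestSpreadingPressure:
    def test_zero_at_zero_activity(self):
        assert spreading_pressure(GAB_32, 305.15, 0.0) == 0.0

    def test_frozen_hand_value(self):
        assert spreading_pressure(GAB_32, 305.15, 0.5) == pytest.approx(
            0.09723310904373472, rel=1e-12
        )

    def test_nonnegative_and_nondecreasing_for_c_above_one(self):
        grid = np.linspace(0.0, 0.9, 50)
        phi = [spreading_pressure(GAB_32, 305.15, a) for a in grid]
        assert all(p >= 0 for p in phi)
        assert all(x <= y for x, y in zip(phi, phi[1:]))

    def test_pole_and_model_guards(self):
        with pytest.raises(DomainError):
            spreading_pressure(GAB_32, 305.15, 1.0 / 0.89)
        with pytest.raises(ValidationError):
            spreading_pressure(SMITH_25, 305.15, 0.5)


class TestHarmonicMean:
    def test_study_temperatures(self):
        assert harmonic_mean_temperature(TEMPS) == pytest.approx(304.40, abs=5e-3)

    def test_identical_temperatures_identity(self):
        assert harmonic_mean_temperature([300.0, 300.0, 300.0]) == pytest.approx(300.0)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            harmonic_mean_temperature([])
        with pytest.raises(ValidationError):
            harmonic_mean_temperature([300.0, -5.0])

    @given(st.lists(st.floats(200.0, 400.0), min_size=1, max_size=8))
    def test_harmonic_below_arithmetic(self, temps):
        hm = harmonic_mean_temperature(temps)
        am = sum(temps) / len(temps)
        assert hm <= am + 1e-9


class TestCompensation:
    def test_published_line_recovered_exactly(self):
        pts = simulate_compensation_series(324.76, 45.57, list(range(36)))
        fit = compensation_fit(pts, TEMPS)
        assert fit.t_beta == pytest.approx(324.76, rel=1e-9)
        assert fit.dG_beta == pytest.approx(45.57, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.driving == "enthalpy"  # t_hm = 304.40 K < t_beta
        assert fit.applicable
        assert not fit.spontaneous  # dG_beta > 0

    def test_flat_line_returns_zero_slope(self):
        pts = [
            ThermoPoint(float(i), 100.0, float(i), {298.15: 0.5, 310.15: 0.5}, 1.0)
            for i in range(5)
        ]
        fit = compensation_fit(pts, TEMPS)
        assert fit.t_beta == pytest.approx(0.0, abs=1e-9)
        assert fit.dG_beta == pytest.approx(100.0)
        assert fit.driving == "entropy"

    def test_entropy_driven_when_hm_exceeds_slope(self):
        pts = simulate_compensation_series(250.0, 100.0, [0.0, 5.0, 10.0, 15.0])
        fit = compensation_fit(pts, TEMPS)
        assert fit.driving == "entropy"
        assert fit.applicable

    def test_indeterminate_within_tolerance(self):
        t_hm = harmonic_mean_temperature(TEMPS)
        pts = simulate_compensation_series(t_hm + 0.5, 100.0, [0.0, 5.0, 10.0])
        fit = compensation_fit(pts, TEMPS)
        assert not fit.applicable
        assert fit.to_dict()["driving"] == "indeterminate"

    def test_too_few_points_rejected(self):
        pts = simulate_compensation_series(324.76, 45.57, [0.0, 1.0])
        with pytest.raises(ValidationError):
            compensation_fit(pts, TEMPS)

    def test_zero_entropy_variance_degenerate(self):
        pts = [
            ThermoPoint(float(i), 100.0 + i, 5.0, {298.15: 0.5, 310.15: 0.5}, 1.0)
            for i in range(4)
        ]
        with pytest.raises(DegenerateDataError):
            compensation_fit(pts, TEMPS)
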