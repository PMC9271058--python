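"""Carbonate-system solver: constants against literature check values,
pH solving against an independently coded brute-force route, EOS-80 density
against the UNESCO check table."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralvar.carbonate import (
    WaterSample,
    depth_to_pressure,
    equilibrium_constants,
    omega_aragonite,
    seawater_density,
    solve_ph_from_ta_dic,
    total_alkalinity_from_ph_dic,
)

# ----------------------------------------------------------------------
# independent brute-force route, coded separately from the package solver


def bruteforce_ta_residual(ph_grid, dic, ta, k, phosphate=0.0, silicate=0.0):
    """Vectorised alkalinity balance, written independently of the package's
    scalar implementation (numpy array arithmetic from the constant set)."""
    h = np.power(10.0, -np.asarray(ph_grid, dtype=float))
    hfree = h / (1.0 + k.ST / k.KS)
    dic_m, pt, sit = dic * 1e-6, phosphate * 1e-6, silicate * 1e-6
    den = h * h + k.K1 * h + k.K1 * k.K2
    carb = dic_m * (k.K1 * h + 2.0 * k.K1 * k.K2) / den
    borate = k.BT / (1.0 + h / k.KB)
    water = k.KW / h
    denp = h ** 3 + k.KP1 * h ** 2 + k.KP1 * k.KP2 * h + k.KP1 * k.KP2 * k.KP3
    phos = (
        pt * (k.KP1 * k.KP2 * h + 2 * k.KP1 * k.KP2 * k.KP3 - h ** 3) / denp
    )
    sil = sit / (1.0 + h / k.KSi)
    sulf = k.ST / (1.0 + k.KS / hfree)
    fluo = k.FT / (1.0 + k.KF / hfree)
    return (carb + borate + water + phos + sil - hfree - sulf - fluo) * 1e6 - ta


def bruteforce_ph(dic, ta, k, phosphate=0.0, silicate=0.0):
    """Zooming grid scan of the alkalinity balance; no bracketing root finder."""
    lo, hi = 2.0, 12.0
    for _ in range(6):
        grid = np.linspace(lo, hi, 2001)
        res = np.abs(bruteforce_ta_residual(grid, dic, ta, k, phosphate, silicate))
        i = int(np.argmin(res))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
# constants


class TestEquilibriumConstants:
    def test_lueker_check_values(self):
        """pK1/pK2 at S=35, 25 degC match the printed Lueker et al. values."""
        k = equilibrium_constants(25.0, 35.0, 0.0)
        assert -math.log10(k.K1) == pytest.approx(5.8472, abs=2e-4)
        assert -math.log10(k.K2) == pytest.approx(8.9660, abs=2e-4)

    def test_weiss_k0_check_value(self):
        """ln K0 at S=35, 25 degC matches the printed Weiss (1974) value."""
        k = equilibrium_constants(25.0, 35.0, 0.0)
        assert math.log(k.K0) == pytest.approx(-3.5617, abs=2e-4)

    def test_dickson_kb_check_value(self):
        """pKB at S=35, 25 degC matches the printed Dickson (1990b) value."""
        k = equilibrium_constants(25.0, 35.0, 0.0)
        assert -math.log10(k.KB) == pytest.approx(8.5975, abs=2e-4)

    def test_mucci_aragonite_solubility(self):
        """Ksp_arag at S=35, 25 degC is the standard 6.48e-7 mol2 kg-2."""
        k = equilibrium_constants(25.0, 35.0, 0.0)
        assert k.Ksp_arag == pytest.approx(6.48e-7, rel=5e-3)

    def test_ordering_and_positivity(self):
        k = equilibrium_constants(11.4, 32.5, 302.0)
        assert k.K1 > k.K2 > 0
        assert min(k.KB, k.KW, k.KS, k.KF, k.KSi, k.Ksp_arag, k.BT, k.Ca) > 0

    def test_pressure_factor_identity_at_surface(self):
        """P=0 and the P->0 limit agree: the pressure correction is identity."""
        k0 = equilibrium_constants(10.0, 33.0, 0.0)
        k_eps = equilibrium_constants(10.0, 33.0, 1e-9)
        for name in ("K1", "K2", "KB", "KW", "KS", "KF", "Ksp_arag"):
            assert getattr(k0, name) == pytest.approx(getattr(k_eps, name), rel=1e-12)

    def test_pressure_correction_matches_direct_polynomial(self):
        """The K1 factor at depth equals exp((-dV + 0.5*dk*P)P/RT) recomputed
        here from the Millero coefficients."""
        t, s, p = 11.4, 32.5, 302.0
        k0 = equilibrium_constants(t, s, 0.0)
        kp = equilibrium_constants(t, s, p)
        tk, pbar = t + 273.15, p / 10.0
        dv = -25.50 + 0.1271 * t
        dk = (-3.08 + 0.0877 * t) / 1000.0
        expected = math.exp((-dv + 0.5 * dk * pbar) * pbar / (83.14472 * tk))
        # compare on the seawater scale, where the correction is applied
        ratio = (kp.K1 / kp.sws_to_total) / (k0.K1 / k0.sws_to_total)
        assert ratio == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "kwargs", [dict(temperature=50.0), dict(salinity=60.0), dict(pressure=-1.0)]
    )
    def test_out_of_range_inputs_rejected(self, kwargs):
        args = dict(temperature=10.0, salinity=33.0, pressure=0.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            equilibrium_constants(**args)


# ----------------------------------------------------------------------
# solver


class TestPhSolver:
    def test_forward_inverse_identity(self):
        """TA computed at pH 8 solves back to pH 8 within 1e-6."""
        k = equilibrium_constants(12.0, 32.0, 0.0)
        ta = total_alkalinity_from_ph_dic(8.0, 2000.0, k)
        sample = WaterSample("X", "s", 12.0, 32.0, 0.0, ta=ta, dic=2000.0)
        assert solve_ph_from_ta_dic(sample, k).ph_total == pytest.approx(8.0, abs=1e-6)

    def test_matches_grid_scan_oracle(self):
        """Brent solution equals the independent zooming grid scan."""
        k = equilibrium_constants(25.0, 35.0, 0.0)
        sample = WaterSample("X", "s", 25.0, 35.0, 0.0, ta=2300.0, dic=2000.0)
        ph = solve_ph_from_ta_dic(sample, k).ph_total
        assert ph == pytest.approx(bruteforce_ph(2000.0, 2300.0, k), abs=1e-5)

    def test_speciation_closure(self):
        """CO2* + HCO3 + CO3 recovers DIC to < 0.01 umol kg-1."""
        sample = WaterSample("X", "s", 11.4, 32.5, 302.0, ta=2280.0, dic=2290.0,
                             phosphate=1.5, silicate=15.0)
        state = solve_ph_from_ta_dic(sample)
        assert abs(state.dic - sample.dic) < 1e-2

    def test_monotonicity_in_ta_and_dic(self):
        """pH rises with TA at fixed DIC and falls with DIC at fixed TA."""
        k = equilibrium_constants(12.0, 32.0, 0.0)

        def ph(ta, dic):
            return solve_ph_from_ta_dic(
                WaterSample("X", "s", 12.0, 32.0, 0.0, ta=ta, dic=dic), k
            ).ph_total

        tas = [2100.0, 2200.0, 2300.0]
        assert ph(tas[0], 2000.0) < ph(tas[1], 2000.0) < ph(tas[2], 2000.0)
        dics = [1900.0, 2000.0, 2100.0]
        assert ph(2300.0, dics[0]) > ph(2300.0, dics[1]) > ph(2300.0, dics[2])

    @settings(max_examples=100, deadline=None)
    @given(
        ph=st.floats(7.2, 8.6),
        dic=st.floats(1800.0, 2300.0),
        t=st.floats(5.0, 25.0),
        s=st.floats(28.0, 35.0),
        po4=st.floats(0.0, 3.0),
        sio4=st.floats(0.0, 50.0),
    )
    def test_roundtrip_property(self, ph, dic, t, s, po4, sio4):
        """Forward TA then inverse solve recovers any valid pH within 1e-6."""
        k = equilibrium_constants(t, s, 0.0)
        ta = total_alkalinity_from_ph_dic(ph, dic, k, po4, sio4)
        sample = WaterSample("X", "s", t, s, 0.0, ta=ta, dic=dic,
                             phosphate=po4, silicate=sio4)
        solved = solve_ph_from_ta_dic(sample, k).ph_total
        assert solved == pytest.approx(ph, abs=1e-6)

    def test_no_root_raises(self):
        sample = WaterSample("X", "s", 12.0, 32.0, 0.0, ta=20000.0, dic=10.0)
        with pytest.raises(ValueError, match="no pH root"):
            solve_ph_from_ta_dic(sample)


class TestOmega:
    def test_definition_and_linearity(self):
        k = equilibrium_constants(12.0, 32.0, 0.0)
        co3_at_unity = k.Ksp_arag / k.Ca * 1e6
        assert omega_aragonite(co3_at_unity, k) == pytest.approx(1.0, rel=1e-12)
        assert omega_aragonite(2 * co3_at_unity, k) == pytest.approx(2.0, rel=1e-12)

    def test_shallow_supersaturated_deep_undersaturated(self, scenario):
        """The scenario's deep bottle resolves to Omega < 1, a shallow
        mid-fjord summer bottle to Omega > 1."""
        import coralvar as cv

        deep, _ = cv.gen_water_samples(scenario, "Ed", "summer", t_mean=11.4)
        shallow, _ = cv.gen_water_samples(scenario, "C", "summer", t_mean=13.0)
        omega_deep = solve_ph_from_ta_dic(deep).omega_arag
        omega_shallow = solve_ph_from_ta_dic(shallow).omega_arag
        assert omega_deep < 1.0 < omega_shallow


# ----------------------------------------------------------------------
# equation of state and pressure


class TestSeawaterDensity:
    @pytest.mark.parametrize(
        "t,s,p,expected",
        [
            (5.0, 0.0, 0.0, 999.96675),
            (5.0, 35.0, 0.0, 1027.67547),
            (25.0, 35.0, 10000.0, 1062.53817),
        ],
    )
    def test_unesco_check_values(self, t, s, p, expected):
        assert seawater_density(t, s, p) == pytest.approx(expected, abs=1e-3)

    def test_thermal_expansion(self):
        """At S=35 surface pressure, density falls monotonically over 5-30 degC."""
        rhos = [seawater_density(t, 35.0) for t in np.arange(5.0, 30.5, 0.5)]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))

    def test_haline_contraction(self):
        """Density rises with salinity across the fjord range 28-34."""
        rhos = [seawater_density(12.0, s) for s in np.arange(28.0, 34.5, 0.5)]
        assert all(a < b for a, b in zip(rhos, rhos[1:]))


class TestDepthToPressure:
    def test_surface_is_zero(self):
        assert depth_to_pressure(0.0) == 0.0

    def test_fjord_depth(self):
        """300 m at 42 degrees S is within 1% of 300 x 1.007 dbar."""
        assert depth_to_pressure(300.0, -42.0) == pytest.approx(302.1, rel=0.01)

    def test_monotone(self):
        assert depth_to_pressure(300.0) > depth_to_pressure(20.0) > 0

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_to_pressure(-5.0)
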