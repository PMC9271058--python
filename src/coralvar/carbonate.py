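"""Seawater CO2-system speciation from the TA + DIC pair, on the total pH scale.

The fjord water samples carry total alkalinity (TA), dissolved inorganic
carbon (DIC) and nutrients at in-situ temperature, salinity and pressure.
This module resolves the full carbonate system from that pair: total-scale
pH, pCO2, bicarbonate/carbonate concentrations and the aragonite saturation
state Omega_arag = [Ca2+][CO3 2-]/Ksp_arag.

Constant choices follow the conventional open-ocean configuration: carbonic
acid after Lueker et al. (2000, total scale), bisulfate after Dickson
(1990a), total boron after Uppstroem (1974), boric acid after Dickson
(1990b), water after Millero (1995), fluoride after Perez & Fraga (1987),
phosphoric/silicic acids after Millero (1995), CO2 solubility after Weiss
(1974), aragonite solubility after Mucci (1983) and calcium after Riley &
Tongudai (1967).  Pressure corrections use the Millero (1995) polynomial
form; the correction factor is exactly 1 at 0 dbar.

Also provided: EOS-80 (UNESCO 1983) seawater density, needed by the
buoyant-weight calcification workflow, and a Saunders (1981) hydrostatic
depth-to-pressure conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from scipy.optimize import brentq

__all__ = [
    "WaterSample",
    "ConstantSet",
    "CarbonateState",
    "equilibrium_constants",
    "solve_ph_from_ta_dic",
    "total_alkalinity_from_ph_dic",
    "omega_aragonite",
    "seawater_density",
    "depth_to_pressure",
]

# gas constant in cm3 bar K-1 mol-1, as used by the Millero pressure polynomials
_RGAS = 83.14472

#: default deployment latitude (Comau Fjord, northern Chilean Patagonia)
DEFAULT_LATITUDE = -42.0


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside valid range [{lo}, {hi}]")


@dataclass(frozen=True)
class WaterSample:
    """One discrete bottle sample: the measured inputs of the CO2 system.

    TA, DIC and nutrients are in umol kg-1; temperature in degC (in situ),
    salinity on the practical scale, pressure in dbar.
    """

    station_id: str
    season: str
    temperature: float
    salinity: float
    pressure: float
    ta: float
    dic: float
    phosphate: float = 0.0
    silicate: float = 0.0

    def __post_init__(self) -> None:
        _check_range("temperature", self.temperature, -2.0, 40.0)
        _check_range("salinity", self.salinity, 0.0, 45.0)
        if self.pressure < 0:
            raise ValueError(f"pressure={self.pressure!r} must be >= 0 dbar")
        if self.ta <= 0 or self.dic <= 0:
            raise ValueError("TA and DIC must be positive (umol kg-1)")
        if self.phosphate < 0 or self.silicate < 0:
            raise ValueError("nutrient concentrations must be >= 0")


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants (mol kg-1 scales) and salinity-derived totals.

    All acid constants are reported on the total hydrogen-ion scale except
    KS (free scale, used with free [H+] in the bisulfate term) and KF
    (free scale, fluoride term).  Totals BT, ST, FT and Ca are mol kg-1.
    """

    temperature: float
    salinity: float
    pressure: float
    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    KP1: float
    KP2: float
    KP3: float
    KSi: float
    Ksp_arag: float
    BT: float
    ST: float
    FT: float
    Ca: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("temperature", "pressure"):
                continue
            if v <= 0:
                raise ValueError(f"constant {f.name} must be positive, got {v!r}")
        if self.K1 <= self.K2:
            raise ValueError("K1 must exceed K2")

    @property
    def sws_to_total(self) -> float:
        """Conversion factor [H]total/[H]sws at these conditions."""
        free_to_total = 1.0 + self.ST / self.KS
        return free_to_total / (free_to_total + self.FT / self.KF)


@dataclass(frozen=True)
class CarbonateState:
    """Resolved CO2-system speciation for one water sample.

    Concentrations in umol kg-1, pCO2 in uatm, pH on the total scale.
    """

    ph_total: float
    pco2: float
    co2_aq: float
    hco3: float
    co3: float
    omega_arag: float

    def __post_init__(self) -> None:
        if not (2.0 < self.ph_total < 12.0):
            raise ValueError(f"solved pH {self.ph_total!r} outside (2, 12)")
        if self.omega_arag <= 0:
            raise ValueError("omega_arag must be positive")

    @property
    def dic(self) -> float:
        """DIC closure: CO2* + HCO3 + CO3 (umol kg-1)."""
        return self.co2_aq + self.hco3 + self.co3


# ----------------------------------------------------------------------
# equilibrium constants


def _pressure_factor(deltaV: float, kappa: float, pbar: float, tk: float) -> float:
    """exp(-(dV/RT) P + (0.5 dk/RT) P^2); identically 1 at P = 0."""
    return math.exp((-deltaV + 0.5 * kappa * pbar) * pbar / (_RGAS * tk))


def equilibrium_constants(
    temperature: float, salinity: float, pressure: float = 0.0
) -> ConstantSet:
    """Full constant set at in-situ T (degC), S (practical) and P (dbar).

    Constants are first evaluated at surface pressure on their native
    scales, converted to the seawater scale, pressure-corrected with the
    Millero (1995) molal-volume polynomials, and converted to the total
    scale using the pressure-corrected KS and KF.
    """
    _check_range("temperature", temperature, -2.0, 40.0)
    _check_range("salinity", salinity, 0.0, 45.0)
    if pressure < 0:
        raise ValueError(f"pressure={pressure!r} must be >= 0 dbar")

    t = temperature
    s = salinity
    tk = t + 273.15
    lntk = math.log(tk)
    sqs = math.sqrt(s)
    # ionic strength of seawater on the molality scale
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    sqi = math.sqrt(ion)

    # salinity-proportional totals, mol kg-1
    bt = 0.0004157 * s / 35.0  # Uppstroem 1974
    st = (0.14 / 96.062) * (s / 1.80655)  # Morris & Riley 1966
    ft = (0.000067 / 18.998) * (s / 1.80655)  # Riley 1965
    ca = (0.02128 / 40.087) * (s / 1.80655)  # Riley & Tongudai 1967

    # KS, Dickson (1990a), free scale, mol kg-1
    lnks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * lntk
        + (-13856.0 / tk + 324.57 - 47.986 * lntk) * sqi
        + (35474.0 / tk - 771.54 + 114.723 * lntk) * ion
        - (2698.0 / tk) * ion ** 1.5
        + (1776.0 / tk) * ion ** 2
        + math.log(1.0 - 0.001005 * s)
    )
    ks = math.exp(lnks)

    # KF, Perez & Fraga (1987), total scale -> free scale
    kf_total = math.exp(874.0 / tk - 9.68 + 0.111 * sqs)
    kf = kf_total / (1.0 + st / ks)

    # surface-pressure SWS <-> total factor
    free_to_total0 = 1.0 + st / ks
    sws_to_total0 = free_to_total0 / (free_to_total0 + ft / kf)

    # K0, Weiss (1974), mol kg-1 atm-1 (pH-scale free)
    tk100 = tk / 100.0
    k0 = math.exp(
        -60.2409
        + 93.4517 / tk100
        + 23.3585 * math.log(tk100)
        + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100 ** 2)
    )

    # K1, K2, Lueker et al. (2000), total scale, mol kg-1
    pk1 = 3633.86 / tk - 61.2172 + 9.6777 * lntk - 0.011555 * s + 0.0001152 * s ** 2
    pk2 = 471.78 / tk + 25.929 - 3.16967 * lntk - 0.01781 * s + 0.0001122 * s ** 2
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # KB, Dickson (1990b), total scale
    lnkb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s ** 1.5 - 0.0996 * s ** 2) / tk
        + 148.0248
        + 137.1942 * sqs
        + 1.62142 * s
        - (24.4344 + 25.085 * sqs + 0.2474 * s) * lntk
        + 0.053105 * sqs * tk
    )
    kb = math.exp(lnkb)

    # KW, Millero (1995), seawater scale
    lnkw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * lntk
        + (118.67 / tk - 5.977 + 1.0495 * lntk) * sqs
        - 0.01615 * s
    )
    kw = math.exp(lnkw)

    # phosphoric acid, Millero (1995), seawater scale
    kp1 = math.exp(
        -4576.752 / tk
        + 115.525
        - 18.453 * lntk
        + (-106.736 / tk + 0.69171) * sqs
        + (-0.65643 / tk - 0.01844) * s
    )
    kp2 = math.exp(
        -8814.715 / tk
        + 172.0883
        - 27.927 * lntk
        + (-160.340 / tk + 1.3566) * sqs
        + (0.37335 / tk - 0.05778) * s
    )
    kp3 = math.exp(
        -3070.75 / tk
        - 18.141
        + (17.27039 / tk + 2.81197) * sqs
        + (-44.99486 / tk - 0.09984) * s
    )

    # silicic acid, Millero (1995), seawater scale (ionic-strength form)
    ksi = math.exp(
        -8904.2 / tk
        + 117.385
        - 19.334 * lntk
        + (-458.79 / tk + 3.5913) * sqi
        + (188.74 / tk - 1.5998) * ion
        + (-12.1652 / tk + 0.07871) * ion ** 2
        + math.log(1.0 - 0.001005 * s)
    )

    # aragonite solubility, Mucci (1983), mol2 kg-2
    log10ksp = (
        -171.945
        - 0.077993 * tk
        + 2903.293 / tk
        + 71.595 * math.log10(tk)
        + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqs
        - 0.10018 * s
        + 0.0059415 * s ** 1.5
    )
    ksp = 10.0 ** log10ksp

    if pressure > 0:
        pbar = pressure / 10.0

        def fac(v0, v1, v2, k0_, k1_):
            dv = v0 + v1 * t + v2 * t * t
            dk = (k0_ + k1_ * t) / 1000.0
            return _pressure_factor(dv, dk, pbar, tk)

        # Millero (1995) coefficients, as in the CO2SYS programme family
        f_k1 = fac(-25.50, 0.1271, 0.0, -3.08, 0.0877)
        f_k2 = fac(-15.82, -0.0219, 0.0, 1.13, -0.1475)
        f_kb = fac(-29.48, 0.1622, 0.002608, -2.84, 0.0)
        f_kw = fac(-20.02, 0.1119, -0.001409, -5.13, 0.0794)
        f_ks = fac(-18.03, 0.0466, 0.000316, -4.53, 0.0900)
        f_kf = fac(-9.78, -0.0090, -0.000942, -3.91, 0.0540)
        f_kp1 = fac(-14.51, 0.1211, -0.000321, -2.67, 0.0427)
        f_kp2 = fac(-23.12, 0.1758, -0.002647, -5.15, 0.0900)
        f_kp3 = fac(-26.57, 0.2020, -0.003042, -4.08, 0.0714)
        f_ksi = f_kb  # conventional: silicate takes the borate coefficients
        # aragonite = calcite volume change + 2.8 cm3 mol-1
        f_ksp = fac(-48.76 + 2.8, 0.5304, 0.0, -11.76, 0.3692)

        ks *= f_ks
        kf *= f_kf
        free_to_total = 1.0 + st / ks
        sws_to_total = free_to_total / (free_to_total + ft / kf)

        # native-total constants detour via SWS for the pressure step
        k1 = k1 / sws_to_total0 * f_k1 * sws_to_total
        k2 = k2 / sws_to_total0 * f_k2 * sws_to_total
        kb = kb / sws_to_total0 * f_kb * sws_to_total
        # native-SWS constants: correct then convert
        kw = kw * f_kw * sws_to_total
        kp1 = kp1 * f_kp1 * sws_to_total
        kp2 = kp2 * f_kp2 * sws_to_total
        kp3 = kp3 * f_kp3 * sws_to_total
        ksi = ksi * f_ksi * sws_to_total
        ksp *= f_ksp
    else:
        kw *= sws_to_total0
        kp1 *= sws_to_total0
        kp2 *= sws_to_total0
        kp3 *= sws_to_total0
        ksi *= sws_to_total0

    return ConstantSet(
        temperature=temperature,
        salinity=salinity,
        pressure=pressure,
        K0=k0,
        K1=k1,
        K2=k2,
        KB=kb,
        KW=kw,
        KS=ks,
        KF=kf,
        KP1=kp1,
        KP2=kp2,
        KP3=kp3,
        KSi=ksi,
        Ksp_arag=ksp,
        BT=bt,
        ST=st,
        FT=ft,
        Ca=ca,
    )


# ----------------------------------------------------------------------
# TA model and pH solver


def total_alkalinity_from_ph_dic(
    ph_total: float,
    dic: float,
    constants: ConstantSet,
    phosphate: float = 0.0,
    silicate: float = 0.0,
) -> float:
    """Forward total alkalinity (umol kg-1) at a given total-scale pH and DIC.

    Sums the carbonate, borate, water, phosphate, silicate, bisulfate and
    fluoride contributions.  DIC and nutrients in umol kg-1.
    """
    k = constants
    h = 10.0 ** (-ph_total)  # total-scale [H+], mol kg-1
    hfree = h / (1.0 + k.ST / k.KS)

    dic_mol = dic * 1e-6
    pt = phosphate * 1e-6
    sit = silicate * 1e-6

    denom = h * h + k.K1 * h + k.K1 * k.K2
    hco3 = dic_mol * k.K1 * h / denom
    co3 = dic_mol * k.K1 * k.K2 / denom

    balk = k.BT * k.KB / (k.KB + h)
    oh = k.KW / h

    denp = h ** 3 + k.KP1 * h ** 2 + k.KP1 * k.KP2 * h + k.KP1 * k.KP2 * k.KP3
    h3po4 = pt * h ** 3 / denp
    hpo4 = pt * k.KP1 * k.KP2 * h / denp
    po4 = pt * k.KP1 * k.KP2 * k.KP3 / denp
    palk = hpo4 + 2.0 * po4 - h3po4

    sialk = sit * k.KSi / (k.KSi + h)

    hso4 = k.ST / (1.0 + k.KS / hfree)
    hf = k.FT / (1.0 + k.KF / hfree)

    ta_mol = hco3 + 2.0 * co3 + balk + oh + palk + sialk - hfree - hso4 - hf
    return ta_mol * 1e6


def solve_ph_from_ta_dic(
    sample: WaterSample, constants: ConstantSet | None = None
) -> CarbonateState:
    """Solve the total-scale pH from the TA + DIC pair and derive speciation.

    The pH is the Brent root of TA_model(pH) - TA_measured on [2, 12]; the
    residual of the returned root is below 1e-4 umol kg-1.  Raises
    ``ValueError`` if the alkalinity balance has no sign change on the
    bracket and ``ArithmeticError`` on negative speciation.
    """
    k = constants if constants is not None else equilibrium_constants(
        sample.temperature, sample.salinity, sample.pressure
    )

    def residual(ph: float) -> float:
        return (
            total_alkalinity_from_ph_dic(
                ph, sample.dic, k, sample.phosphate, sample.silicate
            )
            - sample.ta
        )

    lo, hi = 2.0, 12.0
    rlo, rhi = residual(lo), residual(hi)
    if rlo * rhi > 0:
        raise ValueError(
            f"no pH root in [2, 12] for TA={sample.ta}, DIC={sample.dic} "
            f"(residuals {rlo:.3g}, {rhi:.3g} umol kg-1)"
        )
    ph = brentq(residual, lo, hi, xtol=1e-10, rtol=8.9e-16)
    if abs(residual(ph)) > 1e-4:
        raise ArithmeticError("pH root did not meet the 1e-4 umol kg-1 residual")

    h = 10.0 ** (-ph)
    denom = h * h + k.K1 * h + k.K1 * k.K2
    co2 = sample.dic * h * h / denom
    hco3 = sample.dic * k.K1 * h / denom
    co3 = sample.dic * k.K1 * k.K2 / denom
    if min(co2, hco3, co3) < 0:
        raise ArithmeticError("negative speciation from solved pH")

    pco2 = co2 * 1e-6 / k.K0 * 1e6  # ideal-gas pCO2, uatm
    omega = k.Ca * (co3 * 1e-6) / k.Ksp_arag
    return CarbonateState(
        ph_total=ph, pco2=pco2, co2_aq=co2, hco3=hco3, co3=co3, omega_arag=omega
    )


def omega_aragonite(co3: float, constants: ConstantSet) -> float:
    """Aragonite saturation Omega = [Ca2+][CO3 2-]/Ksp from [CO3 2-] in umol kg-1."""
    return constants.Ca * (co3 * 1e-6) / constants.Ksp_arag


# ----------------------------------------------------------------------
# equation of state and pressure


def seawater_density(
    temperature: float, salinity: float, pressure: float = 0.0
) -> float:
    """EOS-80 (UNESCO 1983) seawater density in kg m-3 at T (degC, IPTS-68 as
    conventionally fed with modern data), S (practical) and P (dbar)."""
    _check_range("temperature", temperature, -2.0, 40.0)
    _check_range("salinity", salinity, 0.0, 42.0)
    if pressure < 0:
        raise ValueError(f"pressure={pressure!r} must be >= 0 dbar")

    t = temperature
    s = salinity
    # density of the standard mean ocean water limit
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t ** 2
        + 1.001685e-4 * t ** 3
        - 1.120083e-6 * t ** 4
        + 6.536332e-9 * t ** 5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t ** 2
        - 8.2467e-7 * t ** 3
        + 5.3875e-9 * t ** 4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t ** 2
    c = 4.8314e-4
    rho0 = rho_w + a * s + b * s ** 1.5 + c * s ** 2
    if pressure == 0:
        return rho0

    p = pressure / 10.0  # bar
    kw = (
        19652.21
        + 148.4206 * t
        - 2.327105 * t ** 2
        + 1.360477e-2 * t ** 3
        - 5.155288e-5 * t ** 4
    )
    k0 = (
        kw
        + s * (54.6746 - 0.603459 * t + 1.09987e-2 * t ** 2 - 6.1670e-5 * t ** 3)
        + s ** 1.5 * (7.944e-2 + 1.6483e-2 * t - 5.3009e-4 * t ** 2)
    )
    aa = (
        3.239908
        + 1.43713e-3 * t
        + 1.16092e-4 * t ** 2
        - 5.77905e-7 * t ** 3
        + s * (2.2838e-3 - 1.0981e-5 * t - 1.6078e-6 * t ** 2)
        + s ** 1.5 * 1.91075e-4
    )
    bb = (
        8.50935e-5
        - 6.12293e-6 * t
        + 5.2787e-8 * t ** 2
        + s * (-9.9348e-7 + 2.0816e-8 * t + 9.1697e-10 * t ** 2)
    )
    bulk = k0 + aa * p + bb * p ** 2
    return rho0 / (1.0 - p / bulk)


def depth_to_pressure(depth: float, latitude: float = DEFAULT_LATITUDE) -> float:
    """Saunders (1981) hydrostatic pressure (dbar) at a given depth (m).

    Monotone in depth; 0 m maps to exactly 0 dbar.
    """
    if depth < 0:
        raise ValueError(f"depth={depth!r} must be >= 0 m")
    sinlat = math.sin(math.radians(latitude))
    c1 = (5.92 + 5.25 * sinlat ** 2) * 1e-3
    return ((1.0 - c1) - math.sqrt((1.0 - c1) ** 2 - 8.84e-6 * depth)) / 4.42e-6
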