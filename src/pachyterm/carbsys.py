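"""Seawater carbonate-system solver for the alkalinity–DIC input pair.

Computes [CO3^2-], pH (total scale) and calcite saturation state from total
alkalinity and dissolved inorganic carbon, following the de-facto default
constant set of CO2SYS-family tools: K1/K2 of Lueker et al. (2000), borate
from salinity (Uppström 1974), KB of Dickson (1990), KW of Millero (1995),
bisulfate of Dickson (1990), fluoride of Perez & Fraga (1987), calcite
solubility of Mucci (1983), with Millero (1995) pressure corrections.

The solver is a Brent root search on pH in [6, 9.5] of the alkalinity
residual.  Nutrient (phosphate/silicate) alkalinity contributions are not
included; they are negligible for the high-latitude surface and thermocline
waters this package targets.

All concentrations are µmol·kg⁻¹ at the interface; mol·kg⁻¹ internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = ["CarbonateState", "solve_carbonate", "equilibrium_constants"]

GAS_CONSTANT = 83.14472  # cm3 bar mol-1 K-1

PH_BRACKET = (6.0, 9.5)
PH_TOL = 1e-10


class CarbonateSolveError(RuntimeError):
    """Raised when the alkalinity residual has no root in the pH bracket."""


@dataclass(frozen=True)
class CarbonateState:
    """Derived carbonate-system state.

    co3            carbonate-ion concentration, µmol·kg⁻¹
    ph_total       pH on the total hydrogen-ion scale
    omega_calcite  calcite saturation state Ω (dimensionless)
    """

    co3: float
    ph_total: float
    omega_calcite: float | None = None


def _validate(alk: float, dic: float, salinity: float, temperature: float,
              pressure: float) -> None:
    if not (alk > 0 and dic > 0):
        raise ValueError(f"alk and dic must be positive (got alk={alk}, dic={dic})")
    if not (0 < salinity < 45):
        raise ValueError(f"salinity {salinity} outside (0, 45)")
    if not (-3 < temperature < 40):
        raise ValueError(f"temperature {temperature} outside (-3, 40) degC")
    if pressure < 0:
        raise ValueError(f"pressure {pressure} dbar is negative")


def _pressure_factor(delta_v: float, delta_k: float, p_bar: float, tk: float) -> float:
    # ln(K_p/K_0) = -(dV/RT) P + (0.5 dK/RT) P^2   (Millero 1995)
    rt = GAS_CONSTANT * tk
    return math.exp((-delta_v + 0.5 * delta_k * p_bar) * p_bar / rt)


def equilibrium_constants(salinity: float, temperature: float,
                          pressure: float = 0.0) -> dict[str, float]:
    """Total-scale equilibrium constants and seawater totals (mol/kg).

    Returns K1, K2, KB, KW, KS (free scale), KF (free scale), Ksp_calcite,
    and the totals TB, TS, TF, Ca for the given salinity, temperature (°C)
    and pressure (dbar).
    """
    s = salinity
    tk = temperature + 273.15
    tc = temperature
    lnt = math.log(tk)
    sqs = math.sqrt(s)
    p_bar = pressure / 10.0

    # --- totals from salinity
    tb = 0.0004157 * s / 35.0                     # Uppström (1974)
    ts = (0.14 / 96.062) * (s / 1.80655)          # Morris & Riley (1966)
    tf = (0.000067 / 18.998) * (s / 1.80655)      # Riley (1965)
    ca = (0.02128 / 40.087) * (s / 1.80655)       # Riley & Tongudai (1967)

    # --- bisulfate, Dickson (1990a), free scale, mol/kg-SW
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    sqi = math.sqrt(ion)
    ln_ks = (-4276.1 / tk + 141.328 - 23.093 * lnt
             + (-13856.0 / tk + 324.57 - 47.986 * lnt) * sqi
             + (35474.0 / tk - 771.54 + 114.723 * lnt) * ion
             - (2698.0 / tk) * ion ** 1.5
             + (1776.0 / tk) * ion ** 2
             + math.log(1.0 - 0.001005 * s))
    ks = math.exp(ln_ks)

    # --- hydrogen fluoride, Perez & Fraga (1987), total scale
    kf_total = math.exp(874.0 / tk - 9.68 + 0.111 * sqs)

    # --- carbonic acid, Lueker et al. (2000), total scale
    pk1 = 3633.86 / tk - 61.2172 + 9.67770 * lnt - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / tk + 25.9290 - 3.16967 * lnt - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # --- boric acid, Dickson (1990b), total scale
    ln_kb = ((-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s ** 1.5
              - 0.0996 * s * s) / tk
             + 148.0248 + 137.1942 * sqs + 1.62142 * s
             + (-24.4344 - 25.085 * sqs - 0.2474 * s) * lnt
             + 0.053105 * sqs * tk)
    kb = math.exp(ln_kb)

    # --- water, Millero (1995), seawater scale
    ln_kw = (148.9802 - 13847.26 / tk - 23.6521 * lnt
             + (118.67 / tk - 5.977 + 1.0495 * lnt) * sqs - 0.01615 * s)
    kw_sws = math.exp(ln_kw)

    # --- calcite solubility, Mucci (1983), mol^2/kg^2
    log_ksp = (-171.9065 - 0.077993 * tk + 2839.319 / tk + 71.595 * math.log10(tk)
               + (-0.77712 + 0.0028426 * tk + 178.34 / tk) * sqs
               - 0.07711 * s + 0.0041249 * s ** 1.5)
    ksp = 10.0 ** log_ksp

    if p_bar > 0:
        k1 *= _pressure_factor(-25.50 + 0.1271 * tc,
                               (-3.08 + 0.0877 * tc) / 1000.0, p_bar, tk)
        k2 *= _pressure_factor(-15.82 - 0.0219 * tc,
                               (1.13 - 0.1475 * tc) / 1000.0, p_bar, tk)
        kb *= _pressure_factor(-29.48 + 0.1622 * tc - 0.002608 * tc * tc,
                               -2.84 / 1000.0, p_bar, tk)
        kw_sws *= _pressure_factor(-20.02 + 0.1119 * tc - 0.001409 * tc * tc,
                                   (-5.13 + 0.0794 * tc) / 1000.0, p_bar, tk)
        ks *= _pressure_factor(-18.03 + 0.0466 * tc + 0.000316 * tc * tc,
                               (-4.53 + 0.09 * tc) / 1000.0, p_bar, tk)
        kf_total *= _pressure_factor(-9.78 - 0.009 * tc - 0.000942 * tc * tc,
                                     (-3.91 + 0.054 * tc) / 1000.0, p_bar, tk)
        ksp *= _pressure_factor(-48.76 + 0.5304 * tc,
                                (-11.76 + 0.3692 * tc) / 1000.0, p_bar, tk)

    # KF on the free scale for the seawater->total conversion of KW
    kf_free = kf_total * (1.0 + ts / ks)
    sws_to_total = (1.0 + ts / ks) / (1.0 + ts / ks + tf / kf_free)
    kw = kw_sws * sws_to_total

    return {"K1": k1, "K2": k2, "KB": kb, "KW": kw, "KS": ks,
            "KF": kf_total, "Ksp_calcite": ksp,
            "TB": tb, "TS": ts, "TF": tf, "Ca": ca}


def _alkalinity_residual(ph: float, dic: float, alk: float, k: dict[str, float]) -> float:
    h = 10.0 ** (-ph)                      # total scale
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    hco3 = dic * k["K1"] * h / denom
    co3 = dic * k["K1"] * k["K2"] / denom
    b_alk = k["TB"] * k["KB"] / (k["KB"] + h)
    oh = k["KW"] / h
    h_free = h / (1.0 + k["TS"] / k["KS"])
    hso4 = k["TS"] / (1.0 + k["KS"] / h_free)
    hf = k["TF"] / (1.0 + k["KF"] / h)
    return hco3 + 2.0 * co3 + b_alk + oh - h_free - hso4 - hf - alk


def solve_carbonate(alk: float, dic: float, salinity: float, temperature: float,
                    pressure: float = 0.0) -> CarbonateState:
    """Solve the carbonate system from total alkalinity and DIC.

    Parameters
    ----------
    alk, dic : float
        Total alkalinity and dissolved inorganic carbon, µmol·kg⁻¹.
    salinity : float
        Practical salinity.
    temperature : float
        In-situ temperature, °C.
    pressure : float
        Pressure, dbar (0 at the surface).

    Returns
    -------
    CarbonateState with [CO3^2-] (µmol·kg⁻¹), total-scale pH and calcite Ω.
    """
    _validate(alk, dic, salinity, temperature, pressure)
    k = equilibrium_constants(salinity, temperature, pressure)
    alk_mol = alk * 1e-6
    dic_mol = dic * 1e-6

    lo, hi = PH_BRACKET
    f_lo = _alkalinity_residual(lo, dic_mol, alk_mol, k)
    f_hi = _alkalinity_residual(hi, dic_mol, alk_mol, k)
    if f_lo * f_hi > 0:
        raise CarbonateSolveError(
            f"no pH root in [{lo}, {hi}] for alk={alk}, dic={dic}, "
            f"S={salinity}, T={temperature}, P={pressure}")
    ph = brentq(_alkalinity_residual, lo, hi, args=(dic_mol, alk_mol, k),
                xtol=PH_TOL)

    h = 10.0 ** (-ph)
    co3_mol = dic_mol * k["K1"] * k["K2"] / (h * h + k["K1"] * h + k["K1"] * k["K2"])
    omega = k["Ca"] * co3_mol / k["Ksp_calcite"]
    return CarbonateState(co3=co3_mol * 1e6, ph_total=ph, omega_calcite=omega)
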