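"""Seawater carbonate-system speciation from total alkalinity and pH.

Given total alkalinity (TA, umol kg^-1), pH on the total scale, temperature
and salinity, the module computes the full inorganic carbon speciation
(HCO3-, CO3^2-, CO2*), dissolved inorganic carbon, and the CO2 partial
pressure of the water.  The alkalinity balance used is

    TA = [HCO3-] + 2[CO3^2-] + [B(OH)4-] + [OH-] - [H+]

(nutrient contributions omitted; they are below 1 umol kg^-1 at coastal
phosphate/silicate levels and were not measured alongside these carbonate
samples).  Equilibrium constants: K1/K2 from Lueker, Mignot & Keeling (2000,
total scale), K0 from Weiss (1974), KB from Dickson (1990), KW from the DOE
handbook (Millero 1995), total boron from salinity after Uppstrom (1974).
All concentrations are mol kg-SW^-1 internally, umol kg^-1 in the returned
state; pCO2 is reported in uatm without a fugacity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "CarbonateConstants",
    "CarbonateState",
    "constants_for",
    "speciate_from_ta_ph",
    "solve_ph_from_ta_pco2",
]

# input validity bounds (name -> (lo, hi))
_BOUNDS = {
    "salinity": (0.0, 45.0),
    "temp": (-2.0, 40.0),
    "ph": (6.0, 9.0),
}


def _check_bounds(*, ta: float, temp: float, salinity: float, ph: float | None = None) -> None:
    if not ta > 0:
        raise ValueError("ta must be > 0 umol kg^-1")
    vals = {"salinity": salinity, "temp": temp}
    if ph is not None:
        vals["ph"] = ph
    for name, v in vals.items():
        lo, hi = _BOUNDS[name]
        if not (lo < v <= hi) and name == "salinity":
            raise ValueError(f"salinity={v} outside (0, 45]")
        if name != "salinity" and not (lo <= v <= hi):
            raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class CarbonateConstants:
    """Equilibrium constants (mol kg-SW^-1, total pH scale) at given T, S."""

    k0: float  # CO2 solubility, mol kg^-1 atm^-1
    k1: float  # H2CO3* <-> HCO3- + H+
    k2: float  # HCO3- <-> CO3^2- + H+
    kb: float  # B(OH)3 <-> B(OH)4- + H+
    kw: float  # water autoprotolysis
    bt: float  # total boron, mol kg^-1


def constants_for(temp: float, salinity: float) -> CarbonateConstants:
    """Evaluate the constant set at temperature (degC) and practical salinity."""
    tk = temp + 273.15
    s = salinity

    # Weiss (1974), CO2 solubility in seawater, mol kg^-1 atm^-1
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / tk)
        + 23.3585 * math.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    k0 = math.exp(ln_k0)

    # Lueker et al. (2000) refit of Mehrbach constants, total scale, mol kg-SW^-1
    pk1 = 3633.86 / tk - 61.2172 + 9.6777 * math.log(tk) - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / tk + 25.929 - 3.16967 * math.log(tk) - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson (1990) boric acid, total scale
    sr = math.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sr - 77.942 * s + 1.728 * s * sr - 0.0996 * s * s) / tk
        + 148.0248
        + 137.1942 * sr
        + 1.62142 * s
        + (-24.4344 - 25.085 * sr - 0.2474 * s) * math.log(tk)
        + 0.053105 * sr * tk
    )
    kb = math.exp(ln_kb)

    # DOE (1994) / Millero (1995) water dissociation, total scale
    ln_kw = (
        148.9652
        - 13847.26 / tk
        - 23.6521 * math.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * math.log(tk)) * sr
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    # Uppstrom (1974): total boron proportional to salinity
    bt = 0.000416 * s / 35.0

    return CarbonateConstants(k0=k0, k1=k1, k2=k2, kb=kb, kw=kw, bt=bt)


@dataclass(frozen=True)
class CarbonateState:
    """Full carbonate speciation at one (TA, pH, T, S) point.

    Concentrations in umol kg^-1; pco2 in uatm; ph on the total scale.
    """

    ta: float
    ph: float
    temp: float
    salinity: float
    pco2: float
    dic: float
    hco3: float
    co3: float
    co2_star: float

    def alkalinity_residual(self) -> float:
        """TA minus the alkalinity recomputed from the returned speciation, umol kg^-1."""
        k = constants_for(self.temp, self.salinity)
        h = 10.0 ** (-self.ph)
        boh4 = k.bt * k.kb / (k.kb + h) * 1e6
        oh = k.kw / h * 1e6
        return self.ta - (self.hco3 + 2.0 * self.co3 + boh4 + oh - h * 1e6)


def speciate_from_ta_ph(ta: float, ph: float, temp: float, salinity: float) -> CarbonateState:
    """Carbonate system state from total alkalinity (umol kg^-1) and total-scale pH.

    Borate, hydroxide and free-proton terms are subtracted from TA to obtain
    carbonate alkalinity, which together with [H+] fixes HCO3-, CO3^2-, CO2*
    and hence DIC and pCO2 (= CO2*/K0).
    """
    _check_bounds(ta=ta, temp=temp, salinity=salinity, ph=ph)
    k = constants_for(temp, salinity)
    h = 10.0 ** (-ph)  # mol kg^-1
    ta_mol = ta * 1e-6

    boh4 = k.bt * k.kb / (k.kb + h)
    oh = k.kw / h
    ca = ta_mol - boh4 - oh + h  # carbonate alkalinity
    if ca <= 0:
        raise ValueError("carbonate alkalinity non-positive for these inputs")

    # CA = [HCO3] + 2[CO3], with [CO3] = K2 [HCO3] / [H]
    hco3 = ca * h / (h + 2.0 * k.k2)
    co3 = ca * k.k2 / (h + 2.0 * k.k2)
    co2_star = hco3 * h / k.k1
    dic = co2_star + hco3 + co3
    pco2_uatm = co2_star / k.k0 * 1e6

    return CarbonateState(
        ta=ta,
        ph=ph,
        temp=temp,
        salinity=salinity,
        pco2=pco2_uatm,
        dic=dic * 1e6,
        hco3=hco3 * 1e6,
        co3=co3 * 1e6,
        co2_star=co2_star * 1e6,
    )


def solve_ph_from_ta_pco2(ta: float, pco2: float, temp: float, salinity: float) -> float:
    """Total-scale pH from total alkalinity (umol kg^-1) and pCO2 (uatm).

    Bracketed root solve of the alkalinity balance over pH in [6, 9]; useful for
    designing high-CO2 treatments (target pCO2 at measured TA).
    """
    _check_bounds(ta=ta, temp=temp, salinity=salinity)
    if not pco2 > 0:
        raise ValueError("pco2 must be > 0 uatm")
    k = constants_for(temp, salinity)
    ta_mol = ta * 1e-6
    co2_star = k.k0 * pco2 * 1e-6  # mol kg^-1

    def residual(ph: float) -> float:
        h = 10.0 ** (-ph)
        hco3 = k.k1 * co2_star / h
        co3 = k.k2 * hco3 / h
        boh4 = k.bt * k.kb / (k.kb + h)
        oh = k.kw / h
        return hco3 + 2.0 * co3 + boh4 + oh - h - ta_mol

    lo, hi = _BOUNDS["ph"]
    if residual(lo) * residual(hi) > 0:
        raise ValueError("no pH root in [6, 9] for these inputs")
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16))
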