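"""Seawater carbonate-system equilibrium solver.

Given dissolved inorganic carbon (DIC) and total alkalinity (Alk) at a
temperature and salinity, solves the total-scale pH of the alkalinity
balance

    Alk = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]

and returns the full speciation, seawater pCO2 and the Revelle (buffer)
factor.  This is the chemistry through which a 2:1 molar addition of
alkalinity and DIC (the signature of declining CaCO3 production) lowers
seawater pCO2 and draws CO2 from the atmosphere.

Equilibrium-constant dialect (fixed, surface pressure, total pH scale):

* K0  — CO2 solubility, Weiss (1974)
* K1, K2 — carbonic acid, Lueker et al. (2000)
* KB  — boric acid, Dickson (1990)
* KW  — water, Millero (1995)
* total boron — Lee et al. (2010), proportional to salinity

Nutrient (phosphate/silicate) alkalinity terms are omitted: the box model
carries no nutrient state.  Concentrations are handled internally in
mol kg-1; mol m-3 inputs are converted with the fixed density
``constants.RHO_SEAWATER``.  pCO2 is reported in uatm without a fugacity
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import RHO_SEAWATER

__all__ = [
    "SeawaterConditions",
    "CarbonateState",
    "EquilibriumConstants",
    "ChemistrySolverError",
    "equilibrium_constants",
    "solve_system",
    "dic_from_pco2",
    "uptake_efficiency",
]

_PH_MIN, _PH_MAX = 2.0, 12.0


class ChemistrySolverError(RuntimeError):
    """The pH root could not be bracketed for the given inputs."""


@dataclass(frozen=True)
class SeawaterConditions:
    """Ambient seawater state: temperature (degC), salinity (psu), pressure (dbar)."""

    temperature: float = 18.0
    salinity: float = 35.0
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise ValueError(f"temperature {self.temperature} degC outside [-2, 40]")
        if not (20.0 <= self.salinity <= 42.0):
            raise ValueError(f"salinity {self.salinity} outside [20, 42]")
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Thermodynamic constants at one (T, S); all on the total pH scale, mol kg-1."""

    k0: float   # mol kg-1 atm-1
    k1: float
    k2: float
    kb: float
    kw: float
    bt: float   # total boron, mol kg-1


def equilibrium_constants(cond: SeawaterConditions) -> EquilibriumConstants:
    t_k = cond.temperature + 273.15
    s = cond.salinity
    sqrt_s = math.sqrt(s)
    ln_t = math.log(t_k)

    # Weiss (1974) CO2 solubility, mol kg-1 atm-1
    t100 = t_k / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / t100
        + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100 * t100)
    )

    # Lueker et al. (2000) carbonic acid, total scale
    pk1 = 3633.86 / t_k - 61.2172 + 9.6777 * ln_t - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / t_k + 25.929 - 3.16967 * ln_t - 0.01781 * s + 0.0001122 * s * s

    # Dickson (1990) boric acid, total scale
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s) / t_k
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_t
        + 0.053105 * sqrt_s * t_k
    )

    # Millero (1995) water dissociation, total scale
    ln_kw = (
        148.9652
        - 13847.26 / t_k
        - 23.6521 * ln_t
        + sqrt_s * (118.67 / t_k - 5.977 + 1.0495 * ln_t)
        - 0.01615 * s
    )

    # Lee et al. (2010) total boron
    bt = 0.0004326 * s / 35.0

    return EquilibriumConstants(
        k0=math.exp(ln_k0),
        k1=10.0 ** (-pk1),
        k2=10.0 ** (-pk2),
        kb=math.exp(ln_kb),
        kw=math.exp(ln_kw),
        bt=bt,
    )


@dataclass(frozen=True)
class CarbonateState:
    """Solved carbonate system; concentrations share the input units."""

    dic: float
    alk: float
    units: str
    ph: float               # total scale
    pco2: float             # uatm
    co2: float              # CO2* (aqueous CO2 + H2CO3)
    hco3: float
    co3: float
    revelle_factor: float
    conditions: SeawaterConditions


def _to_molkg(value: float, units: str) -> float:
    if units == "umol/kg":
        return value * 1e-6
    if units == "mol/m3":
        return value / RHO_SEAWATER
    raise ValueError(f"unknown units {units!r}; expected 'umol/kg' or 'mol/m3'")


def _from_molkg(value: float, units: str) -> float:
    if units == "umol/kg":
        return value * 1e6
    if units == "mol/m3":
        return value * RHO_SEAWATER
    raise ValueError(f"unknown units {units!r}")


def _alk_residual(h: float, dic: float, alk: float, ks: EquilibriumConstants) -> float:
    denom = h * h + ks.k1 * h + ks.k1 * ks.k2
    carb_alk = dic * (ks.k1 * h + 2.0 * ks.k1 * ks.k2) / denom
    borate = ks.bt * ks.kb / (ks.kb + h)
    return carb_alk + borate + ks.kw / h - h - alk


def _alk_residual_deriv(h: float, dic: float, ks: EquilibriumConstants) -> float:
    denom = h * h + ks.k1 * h + ks.k1 * ks.k2
    num = ks.k1 * h + 2.0 * ks.k1 * ks.k2
    d_carb = dic * (ks.k1 * denom - num * (2.0 * h + ks.k1)) / (denom * denom)
    d_borate = -ks.bt * ks.kb / ((ks.kb + h) ** 2)
    return d_carb + d_borate - ks.kw / (h * h) - 1.0


def solve_h(dic: float, alk: float, ks: EquilibriumConstants, h_guess: float | None = None) -> float:
    """Hydrogen-ion concentration (total scale, mol kg-1) closing the Alk balance.

    Newton iteration from ``h_guess`` when supplied (fast path for repeated
    box-model solves), safeguarded by bracketed Brent on pH in [2, 12].
    """
    h_lo = 10.0 ** (-_PH_MAX)
    h_hi = 10.0 ** (-_PH_MIN)
    if h_guess is not None:
        h = h_guess
        for _ in range(50):
            f = _alk_residual(h, dic, alk, ks)
            df = _alk_residual_deriv(h, dic, ks)
            step = f / df
            h_new = h - step
            if not (h_lo < h_new < h_hi):
                break
            if abs(h_new - h) <= 1e-14 * h_new:
                return h_new
            h = h_new
    f_lo = _alk_residual(h_lo, dic, alk, ks)
    f_hi = _alk_residual(h_hi, dic, alk, ks)
    if f_lo * f_hi > 0:
        raise ChemistrySolverError(
            f"chemistry solver failure: no pH root in [{_PH_MIN}, {_PH_MAX}] "
            f"for DIC={dic!r} mol/kg, Alk={alk!r} mol/kg"
        )
    return brentq(_alk_residual, h_lo, h_hi, args=(dic, alk, ks), xtol=1e-18, rtol=8.9e-16)


def _speciation(dic: float, h: float, ks: EquilibriumConstants) -> tuple[float, float, float]:
    denom = h * h + ks.k1 * h + ks.k1 * ks.k2
    co2 = dic * h * h / denom
    hco3 = dic * ks.k1 * h / denom
    co3 = dic * ks.k1 * ks.k2 / denom
    return co2, hco3, co3


def pco2_from_dic_alk(
    dic: float, alk: float, ks: EquilibriumConstants, h_guess: float | None = None
) -> tuple[float, float]:
    """(pCO2 in uatm, solved h) for DIC/Alk in mol kg-1 — box-model fast path."""
    h = solve_h(dic, alk, ks, h_guess)
    co2 = dic * h * h / (h * h + ks.k1 * h + ks.k1 * ks.k2)
    return co2 / ks.k0 * 1e6, h


def solve_system(
    dic: float,
    alk: float,
    conditions: SeawaterConditions | None = None,
    units: str = "umol/kg",
    with_revelle: bool = True,
) -> CarbonateState:
    """Solve the carbonate system from DIC and Alk.

    Parameters
    ----------
    dic, alk : float
        Dissolved inorganic carbon and total alkalinity in ``units``.
    conditions : SeawaterConditions, optional
        Defaults to 18 degC, S=35, surface pressure.
    units : {"umol/kg", "mol/m3"}
    with_revelle : bool
        Skip the (two extra solves) Revelle diagnostic when False.
    """
    if dic <= 0 or alk <= 0:
        raise ValueError("DIC and Alk must be positive")
    cond = conditions or SeawaterConditions()
    ks = equilibrium_constants(cond)
    dic_kg = _to_molkg(dic, units)
    alk_kg = _to_molkg(alk, units)
    h = solve_h(dic_kg, alk_kg, ks)
    co2, hco3, co3 = _speciation(dic_kg, h, ks)
    pco2 = co2 / ks.k0 * 1e6

    revelle = math.nan
    if with_revelle:
        eps = 1e-4 * dic_kg
        p_plus, _ = pco2_from_dic_alk(dic_kg + eps, alk_kg, ks, h)
        p_minus, _ = pco2_from_dic_alk(dic_kg - eps, alk_kg, ks, h)
        revelle = ((p_plus - p_minus) / (2.0 * eps)) * dic_kg / pco2

    return CarbonateState(
        dic=dic,
        alk=alk,
        units=units,
        ph=-math.log10(h),
        pco2=pco2,
        co2=_from_molkg(co2, units),
        hco3=_from_molkg(hco3, units),
        co3=_from_molkg(co3, units),
        revelle_factor=revelle,
        conditions=cond,
    )


def dic_from_pco2(
    pco2: float,
    alk: float,
    conditions: SeawaterConditions | None = None,
    units: str = "umol/kg",
) -> float:
    """DIC whose equilibrium pCO2 at the given Alk equals ``pco2`` (uatm).

    With [CO2*] fixed by Henry's law the alkalinity balance becomes a
    single monotone equation in H+, solved by bracketed Brent; DIC follows
    from the speciation sum.  Used to initialize preindustrial surface
    boxes at gas-exchange equilibrium.
    """
    if pco2 <= 0 or alk <= 0:
        raise ValueError("pCO2 and Alk must be positive")
    cond = conditions or SeawaterConditions()
    ks = equilibrium_constants(cond)
    alk_kg = _to_molkg(alk, units)
    co2 = ks.k0 * pco2 * 1e-6    # mol kg-1

    def residual(h: float) -> float:
        hco3 = ks.k1 * co2 / h
        co3 = ks.k1 * ks.k2 * co2 / (h * h)
        borate = ks.bt * ks.kb / (ks.kb + h)
        return hco3 + 2.0 * co3 + borate + ks.kw / h - h - alk_kg

    h_lo = 10.0 ** (-_PH_MAX)
    h_hi = 10.0 ** (-_PH_MIN)
    if residual(h_lo) * residual(h_hi) > 0:
        raise ChemistrySolverError(
            f"chemistry solver failure: no pH root for pCO2={pco2!r} uatm, Alk={alk!r} {units}"
        )
    h = brentq(residual, h_lo, h_hi, xtol=1e-18, rtol=8.9e-16)
    dic_kg = co2 + ks.k1 * co2 / h + ks.k1 * ks.k2 * co2 / (h * h)
    return _from_molkg(dic_kg, units)


def uptake_efficiency(
    dic: float,
    alk: float,
    conditions: SeawaterConditions | None = None,
    units: str = "umol/kg",
    rel_step: float = 1e-4,
) -> tuple[float, float, float]:
    """(Revelle factor, dpCO2/dAlk, dpCO2/dDIC) by central finite differences.

    The partial derivatives are per unit of the input concentration units;
    the Revelle factor is the dimensionless (dpCO2/pCO2)/(dDIC/DIC) at
    fixed alkalinity.  dpCO2/dAlk is always negative: added alkalinity
    lowers seawater pCO2, the sign at the heart of the reef feedback.
    """
    cond = conditions or SeawaterConditions()
    ks = equilibrium_constants(cond)
    dic_kg = _to_molkg(dic, units)
    alk_kg = _to_molkg(alk, units)
    pco2, h = pco2_from_dic_alk(dic_kg, alk_kg, ks)

    d_eps = rel_step * dic_kg
    p1, _ = pco2_from_dic_alk(dic_kg + d_eps, alk_kg, ks, h)
    p2, _ = pco2_from_dic_alk(dic_kg - d_eps, alk_kg, ks, h)
    dpdd_kg = (p1 - p2) / (2.0 * d_eps)

    a_eps = rel_step * alk_kg
    p3, _ = pco2_from_dic_alk(dic_kg, alk_kg + a_eps, ks, h)
    p4, _ = pco2_from_dic_alk(dic_kg, alk_kg - a_eps, ks, h)
    dpda_kg = (p3 - p4) / (2.0 * a_eps)

    revelle = dpdd_kg * dic_kg / pco2
    # express derivatives per input unit
    unit_scale = _to_molkg(1.0, units)
    return revelle, dpda_kg * unit_scale, dpdd_kg * unit_scale
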