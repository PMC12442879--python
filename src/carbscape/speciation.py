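"""Seawater carbonate-system speciation on the total pH scale.

The solver works from any of the supported input pairs — (TA, pH_t),
(TA, DIC), (TA, pCO2) — and returns a fully speciated :class:`CarbState`.
The alkalinity balance used throughout is

    TA = [HCO3⁻] + 2[CO3²⁻] + [B(OH)4⁻] + [OH⁻]
         + ([HPO4²⁻] + 2[PO4³⁻] − [H3PO4]) + [SiO(OH)3⁻]
         − [H⁺]_free − [HSO4⁻] − [HF]

with [H⁺] carried on the total scale. Concentrations are μmol kg⁻¹ at the
interface and mol kg⁻¹ internally; the 1e-6 factor is applied exactly once
at each boundary. pCO2 is reported as a plain partial pressure via Henry's
law (CO2 = K0·pCO2) without a fugacity correction; see
:data:`APPLY_FUGACITY` to switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from scipy.optimize import brentq

from .constants import ConstantSet, equilibrium_constants

__all__ = [
    "CarbState",
    "MeanCondition",
    "speciate_from_ta_ph",
    "speciate_from_ta_dic",
    "speciate_from_ta_pco2",
    "speciate_from_dic_ph",
    "speciate_from_dic_pco2",
    "speciate_from_ph_pco2",
    "speciate_from_dic_co2",
    "mean_state",
    "alkalinity_from_ph_dic",
]

#: report pCO2 as fugacity instead of partial pressure (off: the convention
#: used for every number in this package).
APPLY_FUGACITY = False

_PH_BRACKET = (2.0, 12.0)
_DEFAULT_PHOSPHATE = 3.0  # μmol kg⁻¹, assumed when not measured


@dataclass(frozen=True)
class CarbState:
    """One fully speciated carbonate-system condition.

    Concentrations in μmol kg⁻¹ except ``H`` (total-scale mol kg⁻¹) and
    ``pCO2`` (μatm); ``omega_aragonite`` dimensionless.
    """

    TA: float
    DIC: float
    pH_t: float
    H: float
    CO2: float
    HCO3: float
    CO3: float
    pCO2: float
    omega_aragonite: float
    temperature: float
    salinity: float
    silicate: float
    phosphate: float

    def __post_init__(self):
        for name in ("TA", "DIC", "CO2", "HCO3", "CO3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name}={v}")


@dataclass(frozen=True)
class MeanCondition:
    """Per-field mean ± SD over the start and end states of a culture."""

    mean: CarbState
    sd: dict


def _check_env(temperature, salinity, silicate, phosphate):
    if silicate < 0 or phosphate < 0:
        raise ValueError("silicate and phosphate must be non-negative")


def _nutrient_alk(h: float, k: ConstantSet, tsi: float, tp: float) -> float:
    """Silicate + phosphate contributions to TA (mol kg⁻¹), at total-scale h."""
    si_alk = tsi * k.KSi / (k.KSi + h)
    denom = (
        h**3 + k.KP1 * h**2 + k.KP1 * k.KP2 * h + k.KP1 * k.KP2 * k.KP3
    )
    h3po4 = tp * h**3 / denom
    hpo4 = tp * k.KP1 * k.KP2 * h / denom
    po4 = tp * k.KP1 * k.KP2 * k.KP3 / denom
    return si_alk + hpo4 + 2.0 * po4 - h3po4


def _minor_alk(h: float, k: ConstantSet, tsi: float, tp: float) -> float:
    """All non-carbonate alkalinity terms (mol kg⁻¹) at total-scale h."""
    b_alk = k.BT * k.KB / (k.KB + h)
    oh = k.Kw / h
    h_free = h / k.free_to_total()
    hso4 = k.TS / (1.0 + k.KS / h_free)
    hf = k.TF / (1.0 + k.KF / h)
    return b_alk + oh + _nutrient_alk(h, k, tsi, tp) - h_free - hso4 - hf


def _ta_from_h_dic(h: float, dic: float, k: ConstantSet, tsi: float, tp: float) -> float:
    """Model TA (mol kg⁻¹) at total-scale h and DIC (mol kg⁻¹)."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    return hco3 + 2.0 * co3 + _minor_alk(h, k, tsi, tp)


def _assemble(
    h: float,
    dic: float,
    k: ConstantSet,
    tsi: float,
    tp: float,
) -> CarbState:
    """Build a CarbState from total-scale h (mol kg⁻¹) and DIC (mol kg⁻¹)."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    co2 = dic * h * h / denom
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    ta = hco3 + 2.0 * co3 + _minor_alk(h, k, tsi, tp)
    pco2 = co2 / k.K0 * 1e6  # atm -> μatm
    omega = k.Ca * co3 / k.Ksp_arag
    return CarbState(
        TA=ta * 1e6,
        DIC=dic * 1e6,
        pH_t=-math.log10(h),
        H=h,
        CO2=co2 * 1e6,
        HCO3=hco3 * 1e6,
        CO3=co3 * 1e6,
        pCO2=pco2,
        omega_aragonite=omega,
        temperature=k.temperature,
        salinity=k.salinity,
        silicate=tsi * 1e6,
        phosphate=tp * 1e6,
    )


def speciate_from_ta_ph(
    TA: float,
    pH_t: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from measured total alkalinity and total-scale pH.

    Closed form: the carbonate alkalinity left after subtracting borate,
    water, nutrient and acid terms fixes DIC directly. ``TA`` and nutrients
    in μmol kg⁻¹.
    """
    if TA <= 0:
        raise ValueError(f"TA must be positive, got {TA}")
    if not 4.0 <= pH_t <= 11.0:
        raise ValueError(f"pH_t={pH_t} outside supported range [4, 11]")
    _check_env(temperature, salinity, silicate, phosphate)
    k = constants or equilibrium_constants(temperature, salinity)
    h = 10.0 ** (-pH_t)
    ta, tsi, tp = TA * 1e-6, silicate * 1e-6, phosphate * 1e-6
    ca = ta - _minor_alk(h, k, tsi, tp)  # carbonate alkalinity
    if ca <= 0:
        raise ValueError(
            f"negative carbonate alkalinity for TA={TA} μmol/kg, pH_t={pH_t} "
            f"(T={temperature}, S={salinity}): inputs are inconsistent"
        )
    dic = ca * (h * h + k.K1 * h + k.K1 * k.K2) / (k.K1 * h + 2.0 * k.K1 * k.K2)
    return _assemble(h, dic, k, tsi, tp)


def _solve_ph(f, lo=_PH_BRACKET[0], hi=_PH_BRACKET[1], label=""):
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(f"infeasible carbonate-system inputs ({label}): "
                         f"no pH root in [{lo}, {hi}]")
    # xtol 1e-12 in pH keeps the [H+] residual far below 1e-10
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)


def speciate_from_ta_dic(
    TA: float,
    DIC: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from total alkalinity and DIC (both μmol kg⁻¹).

    pH is found by Brent root-finding on the alkalinity residual over
    pH ∈ [2, 12]; the residual is strictly monotone in pH so the root is
    unique. Raises for infeasible pairs (no sign change in the bracket).
    """
    if TA <= 0 or DIC <= 0:
        raise ValueError(f"TA and DIC must be positive, got TA={TA}, DIC={DIC}")
    _check_env(temperature, salinity, silicate, phosphate)
    k = constants or equilibrium_constants(temperature, salinity)
    ta, dic = TA * 1e-6, DIC * 1e-6
    tsi, tp = silicate * 1e-6, phosphate * 1e-6

    def f(ph):
        return _ta_from_h_dic(10.0 ** (-ph), dic, k, tsi, tp) - ta

    ph = _solve_ph(f, label=f"TA={TA}, DIC={DIC}")
    return _assemble(10.0 ** (-ph), dic, k, tsi, tp)


def speciate_from_ta_pco2(
    TA: float,
    pCO2: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from total alkalinity (μmol kg⁻¹) and pCO2 (μatm).

    Dissolved CO2 is fixed by Henry's law (CO2 = K0·pCO2); pH follows from
    root-finding on the alkalinity balance with CO2 held fixed, and DIC is
    then derived.
    """
    if TA <= 0 or pCO2 <= 0:
        raise ValueError(f"TA and pCO2 must be positive, got TA={TA}, pCO2={pCO2}")
    _check_env(temperature, salinity, silicate, phosphate)
    k = constants or equilibrium_constants(temperature, salinity)
    ta = TA * 1e-6
    tsi, tp = silicate * 1e-6, phosphate * 1e-6
    co2 = k.K0 * pCO2 * 1e-6  # μatm -> atm -> mol kg⁻¹

    def f(ph):
        h = 10.0 ** (-ph)
        hco3 = k.K1 * co2 / h
        co3 = k.K1 * k.K2 * co2 / (h * h)
        return hco3 + 2.0 * co3 + _minor_alk(h, k, tsi, tp) - ta

    ph = _solve_ph(f, label=f"TA={TA}, pCO2={pCO2}")
    h = 10.0 ** (-ph)
    dic = co2 * (h * h + k.K1 * h + k.K1 * k.K2) / (h * h)
    return _assemble(h, dic, k, tsi, tp)


def speciate_from_dic_ph(
    DIC: float,
    pH_t: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from DIC (μmol kg⁻¹) and total-scale pH (closed form)."""
    if DIC <= 0:
        raise ValueError(f"DIC must be positive, got {DIC}")
    if not 4.0 <= pH_t <= 11.0:
        raise ValueError(f"pH_t={pH_t} outside supported range [4, 11]")
    _check_env(temperature, salinity, silicate, phosphate)
    k = constants or equilibrium_constants(temperature, salinity)
    return _assemble(10.0 ** (-pH_t), DIC * 1e-6, k, silicate * 1e-6, phosphate * 1e-6)


def speciate_from_dic_co2(
    DIC: float,
    CO2: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from DIC and dissolved CO2 (both μmol kg⁻¹; closed form).

    [H⁺] follows from the quadratic DIC·h² = CO2·(h² + K1·h + K1·K2).
    """
    if DIC <= 0 or CO2 <= 0 or CO2 >= DIC:
        raise ValueError(f"need 0 < CO2 < DIC, got CO2={CO2}, DIC={DIC}")
    _check_env(temperature, salinity, silicate, phosphate)
    k = constants or equilibrium_constants(temperature, salinity)
    dic, co2 = DIC * 1e-6, CO2 * 1e-6
    a = dic - co2
    b = -co2 * k.K1
    c = -co2 * k.K1 * k.K2
    h = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    return _assemble(h, dic, k, silicate * 1e-6, phosphate * 1e-6)


def speciate_from_dic_pco2(
    DIC: float,
    pCO2: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from DIC (μmol kg⁻¹) and pCO2 (μatm)."""
    k = constants or equilibrium_constants(temperature, salinity)
    co2 = k.K0 * pCO2 * 1e-6 * 1e6  # μmol kg⁻¹
    return speciate_from_dic_co2(DIC, co2, temperature, salinity, silicate,
                                 phosphate, constants=k)


def speciate_from_ph_pco2(
    pH_t: float,
    pCO2: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> CarbState:
    """Speciate from total-scale pH and pCO2 (μatm; closed form)."""
    if pCO2 <= 0:
        raise ValueError(f"pCO2 must be positive, got {pCO2}")
    if not 4.0 <= pH_t <= 11.0:
        raise ValueError(f"pH_t={pH_t} outside supported range [4, 11]")
    _check_env(temperature, salinity, silicate, phosphate)
    k = constants or equilibrium_constants(temperature, salinity)
    h = 10.0 ** (-pH_t)
    co2 = k.K0 * pCO2 * 1e-6
    dic = co2 * (h * h + k.K1 * h + k.K1 * k.K2) / (h * h)
    return _assemble(h, dic, k, silicate * 1e-6, phosphate * 1e-6)


def alkalinity_from_ph_dic(
    pH_t: float,
    DIC: float,
    temperature: float,
    salinity: float,
    silicate: float = 0.0,
    phosphate: float = _DEFAULT_PHOSPHATE,
    constants: ConstantSet | None = None,
) -> float:
    """Model total alkalinity (μmol kg⁻¹) at a given pH_t and DIC (μmol kg⁻¹)."""
    k = constants or equilibrium_constants(temperature, salinity)
    return (
        _ta_from_h_dic(10.0 ** (-pH_t), DIC * 1e-6, k, silicate * 1e-6,
                       phosphate * 1e-6)
        * 1e6
    )


def mean_state(start: CarbState, end: CarbState) -> MeanCondition:
    """Arithmetic mean ± SD (n = 2) of every field over a culture's start and
    end states, used as the condition the culture experienced."""
    if start.temperature != end.temperature or start.salinity != end.salinity:
        raise ValueError("start and end states must share temperature and salinity")
    means, sds = {}, {}
    for f in fields(CarbState):
        a, b = getattr(start, f.name), getattr(end, f.name)
        means[f.name] = (a + b) / 2.0
        sds[f.name] = abs(a - b) / math.sqrt(2.0)  # ddof=1, n=2
    return MeanCondition(mean=CarbState(**means), sd=sds)
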