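"""Fitness landscapes over TA×DIC space and OA/OAE scenario analysis.

Projects a fitted growth model across a lattice of (TA, DIC) conditions,
extracts the CO2/H⁺ range over which a species stays within a chosen
fraction of its maximum growth rate (its "optimum", 90% by default),
and maps perturbation scenarios: ocean-acidification pCO2 increases and
ocean-alkalinity-enhancement (OAE) additions of TA with partial air–sea
CO2 re-equilibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import equilibrium_constants
from .kinetics import FitResult, eq1_rate
from .speciation import (
    CarbState,
    speciate_from_dic_co2,
    speciate_from_ta_dic,
    speciate_from_ta_pco2,
)

__all__ = [
    "GridSpec",
    "LandscapeGrid",
    "ScenarioSpec",
    "predict_landscape",
    "optimum_interval",
    "oae_scenario",
    "alkalinity_threshold",
    "oa_threshold",
]

_DTA_MAX = 2000.0  # μmol kg⁻¹, bisection bracket for alkalinity thresholds


@dataclass(frozen=True)
class GridSpec:
    """A regular TA×DIC lattice with its environmental conditions."""

    ta_min: float = 2000.0
    ta_max: float = 3350.0
    ta_step: float = 135.0
    dic_min: float = 1800.0
    dic_max: float = 3666.67
    dic_step: float = 266.667
    temperature: float = 15.0
    salinity: float = 33.06
    silicate: float = 0.0
    phosphate: float = 0.0

    def __post_init__(self):
        if self.ta_min >= self.ta_max or self.dic_min >= self.dic_max:
            raise ValueError("grid min must be below max")
        if self.ta_step <= 0 or self.dic_step <= 0:
            raise ValueError("grid steps must be positive")

    def ta_values(self):
        n = int(round((self.ta_max - self.ta_min) / self.ta_step)) + 1
        return np.linspace(self.ta_min, self.ta_max, n)

    def dic_values(self):
        n = int(round((self.dic_max - self.dic_min) / self.dic_step)) + 1
        return np.linspace(self.dic_min, self.dic_max, n)


@dataclass
class LandscapeGrid:
    """Speciated TA×DIC lattice with predicted (relative) growth.

    ``table`` is tidy: one row per feasible cell with columns ta, dic,
    ph_t, co2, h_nmol, pco2, rate, rel_rate, optimum. Infeasible cells
    (no pH root) are masked out and counted in ``n_infeasible``.
    """

    spec: GridSpec
    table: pd.DataFrame
    fraction: float
    n_infeasible: int


@dataclass(frozen=True)
class ScenarioSpec:
    """An OAE perturbation: baseline (TA, atmospheric pCO2), a TA addition,
    and the air–sea equilibration fractions to evaluate."""

    ta: float = 2300.0  # μmol kg⁻¹
    pco2_atm: float = 423.0  # μatm
    delta_ta: float = 300.0  # μmol kg⁻¹
    fractions: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    temperature: float = 15.0
    salinity: float = 33.06
    dic: float | None = None  # fix baseline DIC instead of air equilibrium

    def __post_init__(self):
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("equilibration fractions must lie in [0, 1]")


def predict_landscape(fit: FitResult, grid: GridSpec,
                      fraction: float = 0.90) -> LandscapeGrid:
    """Predict growth over every feasible cell of the TA×DIC lattice.

    The model depends on the cell only through its CO2 (equivalently H⁺),
    so iso-CO2 contours carry constant predicted rate. Relative rate is
    normalized to the grid maximum (negative predictions floor at 0);
    cells with rel_rate ≥ ``fraction`` are flagged as optimum cells.
    """
    k = equilibrium_constants(grid.temperature, grid.salinity)
    rows = []
    n_bad = 0
    for ta in grid.ta_values():
        for dic in grid.dic_values():
            try:
                st = speciate_from_ta_dic(
                    ta, dic, grid.temperature, grid.salinity,
                    silicate=grid.silicate, phosphate=grid.phosphate,
                    constants=k)
            except ValueError:
                n_bad += 1
                continue
            rate = float(eq1_rate(st.CO2, fit.params))
            rows.append({"ta": ta, "dic": dic, "ph_t": st.pH_t,
                         "co2": st.CO2, "h_nmol": st.H * 1e9,
                         "pco2": st.pCO2, "rate": rate})
    if not rows:
        raise ValueError("every cell of the grid is infeasible")
    tab = pd.DataFrame(rows)
    rmax = tab["rate"].max()
    if rmax <= 0:
        raise ValueError("predicted growth is non-positive over the whole grid")
    tab["rel_rate"] = tab["rate"].clip(lower=0.0) / rmax
    tab["optimum"] = tab["rel_rate"] >= fraction
    return LandscapeGrid(spec=grid, table=tab, fraction=fraction,
                         n_infeasible=n_bad)


def optimum_interval(fit: FitResult, fraction: float = 0.90,
                     reference_dic: float = 2030.0,
                     temperature: float = 15.0, salinity: float = 33.06):
    """CO2 and H⁺ ranges over which growth stays within ``fraction`` of Vmax.

    Returns ``((co2_lo, co2_hi), (h_lo, h_hi))`` with CO2 in μmol kg⁻¹ and
    H⁺ in nmol kg⁻¹; endpoints are found by bracketed root-finding on the
    fitted curve and mapped to H⁺ through speciation at ``reference_dic``.
    For a saturating (S = 0) fit the upper endpoints are infinite.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    p = fit.params
    d = fit.derived
    target = fraction * d.vmax

    def g(c):
        return float(eq1_rate(c, p)) - target

    if d.has_optimum:
        co2_lo = brentq(g, 1e-9 * d.c_opt, d.c_opt, xtol=1e-12)
        hi = d.c_opt
        while g(hi) > 0:
            hi *= 2.0
            if hi > 1e9:  # pragma: no cover
                raise RuntimeError("upper optimum edge not bracketed")
        co2_hi = brentq(g, d.c_opt, hi, xtol=1e-12)
    else:
        # saturating form: rate -> X as c -> inf; crosses f·Vmax once
        co2_lo = p.Y * fraction / (1.0 - fraction)
        co2_hi = math.inf

    def h_at(co2):
        if not math.isfinite(co2):
            return math.inf
        st = speciate_from_dic_co2(reference_dic, co2, temperature, salinity,
                                   silicate=0.0, phosphate=0.0)
        return st.H * 1e9

    return (float(co2_lo), float(co2_hi)), (h_at(co2_lo), h_at(co2_hi))


def oae_scenario(spec: ScenarioSpec) -> list[CarbState]:
    """Carbonate states along an OAE equilibration fan.

    The baseline is TA at equilibrium with the atmosphere (or at
    ``spec.dic`` if given). Adding ``delta_ta`` at constant DIC gives the
    unequilibrated state (fraction 0); for each equilibration fraction f,
    DIC is adjusted so that pCO2 = (1−f)·pCO2_unequil + f·pCO2_atm — a
    linear bridge in pCO2 whose f = 1 end restores atmospheric pCO2.

    Returns ``[baseline, state(f0), state(f1), ...]`` in the order of
    ``spec.fractions``.
    """
    T, S = spec.temperature, spec.salinity
    if spec.dic is not None:
        baseline = speciate_from_ta_dic(spec.ta, spec.dic, T, S,
                                        silicate=0.0, phosphate=0.0)
    else:
        baseline = speciate_from_ta_pco2(spec.ta, spec.pco2_atm, T, S,
                                         silicate=0.0, phosphate=0.0)
    ta_new = spec.ta + spec.delta_ta
    unequil = speciate_from_ta_dic(ta_new, baseline.DIC, T, S,
                                   silicate=0.0, phosphate=0.0)
    out = [baseline]
    for f in spec.fractions:
        target = (1.0 - f) * unequil.pCO2 + f * spec.pco2_atm
        out.append(speciate_from_ta_pco2(ta_new, target, T, S,
                                         silicate=0.0, phosphate=0.0))
    return out


def alkalinity_threshold(fit: FitResult, baseline: ScenarioSpec,
                         fraction: float = 0.90, tol: float = 0.01):
    """Smallest TA addition pushing growth below ``fraction``·Vmax.

    Evaluates the unequilibrated branch (no air–sea exchange): DIC is held
    at the baseline value while TA increases, so CO2 falls monotonically.
    Returns a dict with ``delta_ta`` (μmol kg⁻¹, bisection to ``tol``) and
    the perturbed ``ph_t``, ``co2``, ``pco2``; ``delta_ta`` is None when
    growth never leaves the optimum within +2000 μmol kg⁻¹, and 0.0 when
    the baseline already sits below the optimum edge.
    """
    T, S = baseline.temperature, baseline.salinity
    if baseline.dic is not None:
        base = speciate_from_ta_dic(baseline.ta, baseline.dic, T, S,
                                    silicate=0.0, phosphate=0.0)
    else:
        base = speciate_from_ta_pco2(baseline.ta, baseline.pco2_atm, T, S,
                                     silicate=0.0, phosphate=0.0)
    target = fraction * fit.derived.vmax

    def state(dta):
        return speciate_from_ta_dic(baseline.ta + dta, base.DIC, T, S,
                                    silicate=0.0, phosphate=0.0)

    def g(dta):
        return float(eq1_rate(state(dta).CO2, fit.params)) - target

    if g(0.0) < 0:
        dta = 0.0
    elif g(_DTA_MAX) > 0:
        st = state(_DTA_MAX)
        return {"delta_ta": None, "ph_t": st.pH_t, "co2": st.CO2,
                "pco2": st.pCO2, "fraction": fraction}
    else:
        dta = brentq(g, 0.0, _DTA_MAX, xtol=tol)
    st = state(dta)
    return {"delta_ta": float(dta), "ph_t": st.pH_t, "co2": st.CO2,
            "pco2": st.pCO2, "fraction": fraction}


def oa_threshold(fit: FitResult, fraction: float = 0.90,
                 reference_dic: float = 2030.0, temperature: float = 15.0,
                 salinity: float = 33.06):
    """Upper pCO2/H⁺ bound of the optimum under ocean acidification.

    Maps the upper CO2 edge of :func:`optimum_interval` to pCO2 via the
    CO2 solubility constant and to H⁺ (nmol kg⁻¹) at ``reference_dic``.
    A saturating (S = 0) fit has no decline, hence no upper threshold:
    all values are returned as None.
    """
    if not fit.derived.has_optimum:
        return {"pco2": None, "h_nmol": None, "co2": None,
                "fraction": fraction}
    (lo, hi), (h_lo, h_hi) = optimum_interval(
        fit, fraction, reference_dic, temperature, salinity)
    k = equilibrium_constants(temperature, salinity)
    return {"pco2": hi * 1e-6 / k.K0 * 1e6, "h_nmol": h_hi, "co2": hi,
            "fraction": fraction}
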