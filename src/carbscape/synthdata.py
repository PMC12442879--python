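"""Synthetic carbonate-chemistry growth experiments.

Generates complete batch-culture experiments with the statistical structure
the analysis pipeline assumes: a TA×DIC treatment matrix (11 alkalinity
levels spanning 2000–3350 μmol kg⁻¹ crossed with 8 DIC levels spanning
1800–3666.67 μmol kg⁻¹ at 15 °C, salinity 33.06), growth following the
inhibited Michaelis–Menten optimum curve with additive Gaussian noise,
5–10% DIC drawdown at harvest with the matching nitrate-driven alkalinity
increase, daily fluorescence series with multiplicative lognormal noise,
and silica / photophysiology (Fv/Fm) measurements coupled to the growth
optimum.

The generator writes the same start/end (TA, pH_t) measurement pairs a real
experiment records, so every downstream stage — speciation, growth-rate
estimation, exclusion, model fitting, bootstrap — runs unchanged on
synthetic data. Start and end states satisfy the carbonate-system mass
balance exactly (measurements carry no instrument noise; growth and
biomass proxies carry the noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import equilibrium_constants
from .kinetics import (
    KineticParams,
    derive_kinetics,
    eq1_rate,
    params_from_derived,
)
from .speciation import CarbState, speciate_from_ta_dic

__all__ = [
    "SpeciesKineticProfile",
    "ExperimentDesign",
    "CANONICAL_PROFILES",
    "design_matrix",
    "simulate_culture",
    "simulate_experiment",
]

# mol NO3⁻ consumed per mol C fixed (Redfield 16:106)
_N_TO_C = 16.0 / 106.0
# carbon quota, μmol C per cell (order 10 pmol, a mid-sized diatom)
_C_QUOTA = 1e-5
# biogenic silica : carbon ratio of diatom biomass
_SI_TO_C = 0.13
# inoculum biomass expressed as its DIC-drawdown equivalent, μmol C kg⁻¹
_B0 = 2.0


@dataclass(frozen=True)
class SpeciesKineticProfile:
    """Ground-truth kinetic profile driving the generator for one species.

    ``params`` are the raw optimum-curve parameters; ``sigma_growth`` is the
    additive Gaussian noise on realized growth rate (d⁻¹), ``sigma_f`` the
    multiplicative lognormal noise on fluorescence, and ``sigma_fvfm`` the
    coupling noise between growth and Fv/Fm.
    """

    name: str
    params: KineticParams
    sigma_growth: float = 0.05
    sigma_f: float = 0.05
    sigma_fvfm: float = 0.04

    @classmethod
    def from_derived(cls, name, vmax, k_half, s, **kw):
        return cls(name=name, params=params_from_derived(vmax, k_half, s), **kw)

    @property
    def derived(self):
        return derive_kinetics(self.params)


def _canonical():
    """Five species profiles anchored to reported K½ and S estimates.

    K½ values: T. nitzschioides 1.22, C. affinis 1.21, P. cuspidata 0.90,
    T. rotula 5.55, Melosira sp. 0.44 μmol kg⁻¹; sensitivity S spans
    0.0005 (Melosira sp., least sensitive) to 0.0065 (P. cuspidata, most).
    Maximum rates are plausible coastal-diatom values chosen so the optima
    C_opt fall in the reported 13.8–58.5 μmol kg⁻¹ window.
    """
    return {
        "T_nitzschioides": SpeciesKineticProfile.from_derived(
            "T_nitzschioides", vmax=1.10, k_half=1.22, s=0.0030),
        "C_affinis": SpeciesKineticProfile.from_derived(
            "C_affinis", vmax=1.38, k_half=1.21, s=0.0040),
        "P_cuspidata": SpeciesKineticProfile.from_derived(
            "P_cuspidata", vmax=1.05, k_half=0.90, s=0.0065),
        "T_rotula": SpeciesKineticProfile.from_derived(
            "T_rotula", vmax=1.00, k_half=5.55, s=0.0017),
        "Melosira_sp": SpeciesKineticProfile.from_derived(
            "Melosira_sp", vmax=0.80, k_half=0.44, s=0.0005),
    }


CANONICAL_PROFILES: dict[str, SpeciesKineticProfile] = _canonical()


@dataclass(frozen=True)
class ExperimentDesign:
    """The TA×DIC treatment matrix and shared environmental conditions."""

    ta_levels: tuple = tuple(np.linspace(2000.0, 3350.0, 11))
    dic_levels: tuple = tuple(np.linspace(1800.0, 3666.67, 8))
    temperature: float = 15.0
    salinity: float = 33.06
    nitrate: float = 48.0  # μmol kg⁻¹ in the medium
    silicate: float = 3.0  # μmol kg⁻¹
    phosphate: float = 3.0  # μmol kg⁻¹
    drawdown: tuple = (0.05, 0.10)  # target DIC drawdown fraction range
    n_treatments: int | None = None  # optional deterministic subsample
    f0: float = 100.0  # initial fluorescence, instrument units

    def __post_init__(self):
        if len(self.ta_levels) < 1 or len(self.dic_levels) < 1:
            raise ValueError("need at least one TA and one DIC level")
        if not (0 < self.drawdown[0] <= self.drawdown[1] < 1):
            raise ValueError(f"invalid drawdown range {self.drawdown}")


def design_matrix(design: ExperimentDesign) -> list[CarbState]:
    """Cross the TA and DIC levels and speciate every feasible cell.

    Cells with no pH root (infeasible TA/DIC pairs) are dropped; a warning
    is raised if fewer than 67 treatments survive. When
    ``design.n_treatments`` is set, an evenly spaced deterministic subsample
    of that size is returned.
    """
    k = equilibrium_constants(design.temperature, design.salinity)
    cells = []
    for ta in design.ta_levels:
        for dic in design.dic_levels:
            try:
                st = speciate_from_ta_dic(
                    ta, dic, design.temperature, design.salinity,
                    silicate=design.silicate, phosphate=design.phosphate,
                    constants=k)
            except ValueError:
                continue
            cells.append(st)
    if len(cells) < 67:
        import warnings

        warnings.warn(
            f"only {len(cells)} feasible treatments (design aims for ≥ 67)")
    if design.n_treatments is not None and design.n_treatments < len(cells):
        idx = np.linspace(0, len(cells) - 1, design.n_treatments).round().astype(int)
        cells = [cells[i] for i in np.unique(idx)]
    return cells


def simulate_culture(profile: SpeciesKineticProfile, condition: CarbState,
                     design: ExperimentDesign, seed=None,
                     culture_id: str = "c000") -> dict:
    """Simulate one culture vessel at one speciated condition.

    Returns a flat record (dict) with the start/end measurements, the
    fluorescence series (under ``"series_day"``/``"series_f"``), and the
    generated biology. The realized growth rate responds to the *mean* CO2
    of the vessel over the growth period, matching how the analysis
    attributes conditions to cultures.
    """
    rng = np.random.default_rng(seed)
    k = equilibrium_constants(design.temperature, design.salinity)
    d = profile.derived

    dd = rng.uniform(*design.drawdown)  # target DIC drawdown fraction
    dic_end = condition.DIC * (1.0 - dd)
    drawn_c = condition.DIC * dd  # μmol C kg⁻¹ fixed
    no3_used = min(_N_TO_C * drawn_c, design.nitrate)
    ta_end = condition.TA + no3_used  # +1 TA per NO3⁻ consumed
    dsi_uptake = min(_SI_TO_C * drawn_c, 0.9 * design.silicate)
    dsi_end = design.silicate - dsi_uptake
    end = speciate_from_ta_dic(ta_end, dic_end, design.temperature,
                               design.salinity, silicate=dsi_end,
                               phosphate=design.phosphate, constants=k)
    mean_co2 = 0.5 * (condition.CO2 + end.CO2)
    rate_det = float(eq1_rate(mean_co2, profile.params))
    rate = rate_det + rng.normal(0.0, profile.sigma_growth)

    if rate <= 0.0:
        # zero net growth / mortality: no drawdown, flat-to-declining series
        days = np.arange(0.0, 6.0)
        f = design.f0 * np.exp(min(rate, 0.0) * days) * np.exp(
            rng.normal(0.0, profile.sigma_f, size=days.size))
        end = condition
        dsi_end = design.silicate
        cells = _B0 / _C_QUOTA * float(rng.lognormal(0.0, 0.1))
        bsi = _SI_TO_C * _B0 * float(rng.lognormal(0.0, 0.1))
    else:
        n_days = int(np.clip(np.ceil(np.log(dd * condition.DIC / _B0) / rate),
                             3, 30))
        days = np.arange(0.0, n_days + 1.0)
        f = design.f0 * np.exp(rate * days) * np.exp(
            rng.normal(0.0, profile.sigma_f, size=days.size))
        cells = drawn_c / _C_QUOTA * float(rng.lognormal(0.0, 0.1))
        bsi = _SI_TO_C * drawn_c * float(rng.lognormal(0.0, 0.1))

    fvfm = float(np.clip(0.25 + 0.45 * max(rate_det, 0.0) / d.vmax
                         + rng.normal(0.0, profile.sigma_fvfm), 0.0, 1.0))

    return {
        "species": profile.name,
        "culture_id": culture_id,
        "ta_start": condition.TA,
        "ta_end": end.TA,
        "ph_start": condition.pH_t,
        "ph_end": end.pH_t,
        "temperature": design.temperature,
        "salinity": design.salinity,
        "dsi_start": design.silicate,
        "dsi_end": dsi_end,
        "bsi": bsi,
        "cells_end": cells,
        "fvfm": fvfm,
        "true_rate": rate,
        "series_day": days,
        "series_f": f,
    }


def simulate_experiment(profile: SpeciesKineticProfile,
                        design: ExperimentDesign | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full experiment for one species.

    Returns ``(cultures, fluorescence)`` data frames in the culture-CSV
    schemas consumed by :func:`carbscape.cultures.process_cultures`. Same
    seed → byte-identical tables.
    """
    design = design or ExperimentDesign()
    conditions = design_matrix(design)
    rng = np.random.default_rng(seed)
    cult_rows, flu_rows = [], []
    for i, cond in enumerate(conditions):
        rec = simulate_culture(profile, cond, design,
                               seed=rng.integers(0, 2**31 - 1),
                               culture_id=f"{profile.name}_{i:03d}")
        days, f = rec.pop("series_day"), rec.pop("series_f")
        cult_rows.append(rec)
        for dy, fv in zip(days, f):
            flu_rows.append({"culture_id": rec["culture_id"],
                             "day": dy, "fluorescence": fv})
    return pd.DataFrame(cult_rows), pd.DataFrame(flu_rows)
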