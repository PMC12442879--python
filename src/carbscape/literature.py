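"""Harmonization of published growth vs carbonate-chemistry records.

Published datasets report growth against heterogeneous carbonate-chemistry
descriptions — CO2 directly, or any two of TA / DIC / pH / pCO2. This
module screens records against the inclusion rules (NaOH/HCl manipulation;
more than 3 distinct CO2 levels for model fitting; at least 2 reported
carbonate parameters for landscape placement), converts every eligible
record to a (CO2 μmol kg⁻¹, relative growth) point at the study's own
temperature and salinity, and fits the optimum-curve model per
study–species set plus a pooled "average diatom response".

pH-scale metadata must be declared per record ("total", "free", or
"sws"); an undeclared scale defaults to total with a logged warning, and
missing salinity defaults to 35 with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import equilibrium_constants
from .kinetics import FitResult, fit_growth_model, select_model
from .speciation import (
    speciate_from_dic_pco2,
    speciate_from_dic_ph,
    speciate_from_ph_pco2,
    speciate_from_ta_dic,
    speciate_from_ta_pco2,
    speciate_from_ta_ph,
)

__all__ = [
    "LiteratureRecord",
    "screen_inclusion",
    "harmonize",
    "harmonize_table",
    "fit_all",
]

log = logging.getLogger(__name__)

_DEFAULT_SALINITY = 35.0
_PARAMS = {"ta", "dic", "ph", "pco2", "co2"}


@dataclass
class LiteratureRecord:
    """One published growth observation and its carbonate-chemistry context."""

    study_id: str
    species: str
    growth_rate: float  # d⁻¹
    temperature: float  # °C
    param1_name: str | None = None
    param1_value: float | None = None
    param2_name: str | None = None
    param2_value: float | None = None
    ph_scale: str | None = None  # "total" | "free" | "sws"
    salinity: float | None = None
    manipulation: str | None = None  # e.g. "NaOH/HCl", "bubbling"

    def reported_params(self) -> dict:
        out = {}
        for n, v in ((self.param1_name, self.param1_value),
                     (self.param2_name, self.param2_value)):
            if n is not None and v is not None and not np.isnan(v):
                key = n.lower()
                if key not in _PARAMS:
                    raise ValueError(f"unknown carbonate parameter {n!r}")
                out[key] = float(v)
        return out


def _ph_to_total(ph: float, scale: str | None, temperature: float,
                 salinity: float, study_id: str) -> float:
    """Convert a reported pH to the total scale."""
    k = equilibrium_constants(temperature, salinity)
    if scale is None:
        log.warning("study %s: pH scale undeclared, assuming total scale",
                    study_id)
        return ph
    scale = scale.lower()
    h = 10.0 ** (-ph)
    if scale in ("total", "t"):
        return ph
    if scale == "free":
        return float(-np.log10(h * k.free_to_total()))
    if scale in ("sws", "seawater"):
        return float(-np.log10(h * k.sws_to_total()))
    raise ValueError(f"unsupported pH scale {scale!r} (study {study_id})")


def screen_inclusion(records: list[LiteratureRecord]) -> pd.DataFrame:
    """Apply the inclusion rules per (study, species) set.

    Returns a table with ``model_eligible`` (more than 3 distinct CO2
    levels, after harmonization), ``landscape_eligible`` (≥ 2 reported
    carbonate parameters) and ``manipulation_ok`` (NaOH/HCl or
    unreported) flags. Flags only — no record is dropped here.
    """
    rows = []
    groups: dict = {}
    for r in records:
        groups.setdefault((r.study_id, r.species), []).append(r)
    for (study, species), grp in groups.items():
        co2s = set()
        for r in grp:
            pt = harmonize(r)
            if pt is not None:
                co2s.add(round(pt[0], 6))
        n_params = [len(r.reported_params()) for r in grp]
        manip_ok = all(r.manipulation is None
                       or "naoh" in r.manipulation.lower().replace(" ", "")
                       for r in grp)
        rows.append({
            "study_id": study,
            "species": species,
            "n_records": len(grp),
            "n_co2_levels": len(co2s),
            "model_eligible": len(co2s) > 3 and manip_ok,
            "landscape_eligible": all(n >= 2 for n in n_params) and manip_ok,
            "manipulation_ok": manip_ok,
        })
    return pd.DataFrame(rows)


def harmonize(record: LiteratureRecord):
    """Convert one record to a (CO2 μmol kg⁻¹, growth rate) point.

    CO2 is taken directly when reported; otherwise it is computed from the
    reported parameter pair by speciation at the study's temperature and
    salinity (nutrients zero — literature records rarely report them).
    Returns None, with a logged reason, when the parameters are
    insufficient. Idempotent: re-harmonizing changes nothing.
    """
    p = record.reported_params()
    sal = record.salinity
    if sal is None:
        log.warning("study %s: salinity unreported, assuming %s",
                    record.study_id, _DEFAULT_SALINITY)
        sal = _DEFAULT_SALINITY
    T = record.temperature
    if "co2" in p:
        return float(p["co2"]), record.growth_rate
    if "ph" in p:
        p = dict(p)
        p["ph"] = _ph_to_total(p["ph"], record.ph_scale, T, sal,
                               record.study_id)
    kw = dict(temperature=T, salinity=sal, silicate=0.0, phosphate=0.0)
    try:
        if {"ta", "ph"} <= p.keys():
            st = speciate_from_ta_ph(p["ta"], p["ph"], **kw)
        elif {"ta", "dic"} <= p.keys():
            st = speciate_from_ta_dic(p["ta"], p["dic"], **kw)
        elif {"ta", "pco2"} <= p.keys():
            st = speciate_from_ta_pco2(p["ta"], p["pco2"], **kw)
        elif {"dic", "ph"} <= p.keys():
            st = speciate_from_dic_ph(p["dic"], p["ph"], **kw)
        elif {"dic", "pco2"} <= p.keys():
            st = speciate_from_dic_pco2(p["dic"], p["pco2"], **kw)
        elif {"ph", "pco2"} <= p.keys():
            st = speciate_from_ph_pco2(p["ph"], p["pco2"], **kw)
        else:
            log.info("study %s: insufficient carbonate parameters %s, skipped",
                     record.study_id, sorted(p))
            return None
    except ValueError as e:
        log.info("study %s: speciation failed (%s), skipped",
                 record.study_id, e)
        return None
    return float(st.CO2), record.growth_rate


def harmonize_table(records: list[LiteratureRecord]) -> pd.DataFrame:
    """Harmonize all records; growth normalized per (study, species) to its
    maximum so every modelled rate lies in [0, 1]."""
    rows = []
    for r in records:
        pt = harmonize(r)
        if pt is None:
            continue
        rows.append({"study_id": r.study_id, "species": r.species,
                     "co2": pt[0], "growth_rate": pt[1]})
    tab = pd.DataFrame(rows)
    if tab.empty:
        return tab
    tab["relative_growth"] = tab.groupby(["study_id", "species"])[
        "growth_rate"].transform(lambda g: g / g.max())
    return tab


def fit_all(records: list[LiteratureRecord], seed: int = 0,
            select_reps: int = 200) -> dict:
    """Fit every model-eligible (study, species) set, plus the pooled
    "average diatom response" over all harmonized relative rates.

    The per-set model form is chosen by :func:`select_model` (inhibited
    form when the bootstrap CI of S excludes 0). Returns
    ``{"per_set": {(study, species): FitResult}, "pooled": FitResult}``.
    """
    flags = screen_inclusion(records)
    tab = harmonize_table(records)
    per_set: dict = {}
    for _, fl in flags[flags["model_eligible"]].iterrows():
        sub = tab[(tab["study_id"] == fl["study_id"])
                  & (tab["species"] == fl["species"])]
        pts = np.column_stack([sub["co2"], sub["relative_growth"]])
        model = select_model(pts, seed=seed, n_reps=select_reps)
        per_set[(fl["study_id"], fl["species"])] = fit_growth_model(
            pts, model, seed=seed)
    pooled = None
    if not tab.empty and tab["co2"].nunique() > 3:
        pts = np.column_stack([tab["co2"], tab["relative_growth"]])
        model = select_model(pts, seed=seed, n_reps=select_reps)
        pooled = fit_growth_model(pts, model, seed=seed)
    return {"per_set": per_set, "pooled": pooled}
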