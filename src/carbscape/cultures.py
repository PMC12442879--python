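"""Batch-culture processing: growth rates, exclusions, silica metrics.

Growth rate μ (d⁻¹) is the ordinary least-squares slope of ln(F) against
time, where F is dark-adapted in-vivo chlorophyll-a minimum fluorescence
used as a biomass proxy; a minimum monitored span of 3 days is required.
Cultures with zero net growth or mortality (μ ≤ 0 by default) are flagged
and excluded from model fitting but retained in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .speciation import mean_state, speciate_from_ta_ph

__all__ = [
    "FluorescenceSeries",
    "CultureRecord",
    "growth_rate_from_fluorescence",
    "apply_exclusions",
    "silica_metrics",
    "rsquared",
    "relative_growth",
    "percent_decrease",
    "process_cultures",
]

MIN_SPAN_DAYS = 3.0


@dataclass(frozen=True)
class FluorescenceSeries:
    """Daily pre-dawn fluorescence readings for one culture vessel."""

    day: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        day = np.asarray(self.day, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "F", F)
        if day.size < 2 or day.size != F.size:
            raise ValueError("series needs ≥ 2 matched (day, F) points")
        if np.any(np.diff(day) <= 0):
            raise ValueError("day values must be strictly increasing")

    @property
    def span(self) -> float:
        return float(self.day[-1] - self.day[0])


@dataclass
class CultureRecord:
    """One culture vessel: measurements, series, derived growth and flags."""

    species: str
    culture_id: str
    ta_start: float
    ta_end: float
    ph_start: float
    ph_end: float
    temperature: float
    salinity: float
    dsi_start: float | None = None
    dsi_end: float | None = None
    bsi: float | None = None
    cells_end: float | None = None
    fvfm: float | None = None
    series: FluorescenceSeries | None = None
    growth_rate: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    extras: dict = field(default_factory=dict)


def growth_rate_from_fluorescence(series: FluorescenceSeries) -> float:
    """OLS slope of ln F vs day (d⁻¹). Exact for clean exponential growth.

    Raises when the series spans < 3 days or contains non-positive F.
    """
    if series.span < MIN_SPAN_DAYS:
        raise ValueError(
            f"series spans {series.span:g} d; a minimum of 3 days is required"
        )
    if np.any(series.F <= 0):
        raise ValueError("fluorescence values must be positive")
    slope, _ = np.polyfit(series.day, np.log(series.F), 1)
    return float(slope)


def apply_exclusions(records: list[CultureRecord],
                     threshold: float = 0.0) -> list[CultureRecord]:
    """Flag cultures with zero net growth or mortality (μ ≤ ``threshold``).

    Flagged records stay in the outputs but are barred from model fitting.
    """
    for r in records:
        if r.growth_rate is None:
            continue
        if r.growth_rate < threshold:
            r.excluded, r.exclusion_reason = True, "mortality"
        elif r.growth_rate == threshold:
            r.excluded, r.exclusion_reason = True, "zero net growth"
        else:
            r.excluded, r.exclusion_reason = False, None
    return records


def silica_metrics(record: CultureRecord) -> tuple[float, float]:
    """Per-cell silica metrics: (ΔDSi/cell, BSi/cell).

    ΔDSi/cell = (DSi_start − DSi_end) / cells_end, positive for uptake;
    BSi/cell = BSi / cells_end. Negative uptake is allowed but flagged in
    ``record.extras['negative_dsi_uptake']``.
    """
    if record.cells_end is None or record.cells_end <= 0:
        raise ValueError(f"culture {record.culture_id}: cells_end must be > 0")
    if record.dsi_start is None or record.dsi_end is None:
        raise ValueError(f"culture {record.culture_id}: DSi start/end required")
    delta = (record.dsi_start - record.dsi_end) / record.cells_end
    bsi_per_cell = (record.bsi / record.cells_end
                    if record.bsi is not None else math.nan)
    record.extras["negative_dsi_uptake"] = delta < 0
    return float(delta), float(bsi_per_cell)


def rsquared(x, y) -> float:
    """Coefficient of determination of a simple linear regression of y on x
    (the squared Pearson correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need ≥ 3 matched points")
    if np.allclose(x, x[0]):
        raise ValueError("x must not be constant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def relative_growth(rates, excluded=None) -> np.ndarray:
    """Normalize growth rates to the species' maximum retained rate.

    Excluded records keep their (normalized) value but never set the
    maximum. All retained values land in [0, 1] with the maximum at 1.
    """
    rates = np.asarray(rates, dtype=float)
    if excluded is None:
        excluded = np.zeros(rates.shape, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    retained = rates[~excluded]
    if retained.size == 0 or np.nanmax(retained) <= 0:
        raise ValueError("no retained positive growth rates to normalize by")
    return rates / float(np.nanmax(retained))


def percent_decrease(start: float, end: float) -> float:
    """Relative decrease from ``start`` to ``end``, in percent.

    E.g. growth falling 1.38 → 0.18 d⁻¹ is an 87% decrease.
    """
    if start == 0:
        raise ValueError("start value must be non-zero")
    return (start - end) / start * 100.0


def process_cultures(cultures: pd.DataFrame, fluorescence: pd.DataFrame,
                     exclusion_threshold: float = 0.0) -> pd.DataFrame:
    """Build the analysis-ready table from raw culture and fluorescence CSVs.

    ``cultures`` has one row per culture (see the simulator for the schema);
    ``fluorescence`` is long-format (culture_id, day, fluorescence). Start
    and end carbonate states are speciated from measured (TA, pH_t), the
    culture-mean condition is attached, growth rates are computed from the
    ln-slope, exclusions applied, and silica metrics added.
    """
    required = {"species", "culture_id", "ta_start", "ta_end", "ph_start",
                "ph_end", "temperature", "salinity"}
    missing = required - set(cultures.columns)
    if missing:
        raise ValueError(f"cultures table missing columns: {sorted(missing)}")
    for col in ("culture_id", "day", "fluorescence"):
        if col not in fluorescence.columns:
            raise ValueError(f"fluorescence table missing column: {col}")

    rows = []
    for _, row in cultures.iterrows():
        sub = fluorescence[fluorescence["culture_id"] == row["culture_id"]]
        sub = sub.sort_values("day")
        series = FluorescenceSeries(sub["day"].to_numpy(),
                                    sub["fluorescence"].to_numpy())
        mu = growth_rate_from_fluorescence(series)
        sil = float(row.get("silicate", row.get("dsi_start", 0.0)) or 0.0)
        start = speciate_from_ta_ph(row["ta_start"], row["ph_start"],
                                    row["temperature"], row["salinity"],
                                    silicate=sil)
        end = speciate_from_ta_ph(row["ta_end"], row["ph_end"],
                                  row["temperature"], row["salinity"],
                                  silicate=float(row.get("dsi_end", sil) or sil))
        mc = mean_state(start, end)
        rec = dict(row)
        rec["growth_rate"] = mu
        for name in ("CO2", "HCO3", "CO3", "DIC", "TA", "pH_t", "pCO2",
                     "omega_aragonite"):
            rec[f"mean_{name.lower()}"] = getattr(mc.mean, name)
            rec[f"sd_{name.lower()}"] = mc.sd[name]
        rec["mean_h_nmol"] = mc.mean.H * 1e9
        if (row.get("cells_end") or 0) > 0 and pd.notna(row.get("dsi_start")):
            cr = CultureRecord(
                species=row["species"], culture_id=row["culture_id"],
                ta_start=row["ta_start"], ta_end=row["ta_end"],
                ph_start=row["ph_start"], ph_end=row["ph_end"],
                temperature=row["temperature"], salinity=row["salinity"],
                dsi_start=row.get("dsi_start"), dsi_end=row.get("dsi_end"),
                bsi=row.get("bsi"), cells_end=row.get("cells_end"),
            )
            rec["delta_dsi_per_cell"], rec["bsi_per_cell"] = silica_metrics(cr)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["excluded"] = out["growth_rate"] <= exclusion_threshold
    out["exclusion_reason"] = np.where(
        out["growth_rate"] < exclusion_threshold, "mortality",
        np.where(out["growth_rate"] == exclusion_threshold,
                 "zero net growth", ""))
    for sp, grp in out.groupby("species"):
        out.loc[grp.index, "relative_growth"] = relative_growth(
            grp["growth_rate"].to_numpy(), grp["excluded"].to_numpy())
    return out
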