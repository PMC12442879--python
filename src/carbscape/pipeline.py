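"""End-to-end pipeline: simulate/ingest → process → fit → landscape → thresholds.

A :class:`RunConfig` (fully serializable; loadable from YAML) plus input
tables determine every output. Outputs are CSV/JSON with a manifest
recording input hashes, seed, package version and stage warnings, so a
run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cultures import process_cultures
from .kinetics import FitResult, bootstrap_ci, fit_growth_model, select_model
from .landscape import (
    GridSpec,
    ScenarioSpec,
    alkalinity_threshold,
    oa_threshold,
    optimum_interval,
    predict_landscape,
)
from .synthdata import CANONICAL_PROFILES, ExperimentDesign, simulate_experiment

__all__ = ["RunConfig", "run_pipeline", "fit_result_to_dict"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Either point ``cultures_csv``/``fluorescence_csv`` at measured data, or
    set ``simulate`` to a list of canonical profile names to generate the
    inputs first.
    """

    out_dir: str = "run_out"
    seed: int = 0
    cultures_csv: str | None = None
    fluorescence_csv: str | None = None
    simulate: list = field(default_factory=list)
    model: str = "auto"  # "eq1" | "eq2" | "auto"
    boot_mode: str = "nonparametric"
    boot_reps: int = 1000
    fraction: float = 0.90
    grid: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    exclusion_threshold: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "model_id": fit.model_id,
        "params": {"X": fit.params.X, "Y": fit.params.Y, "S": fit.params.S},
        "derived": {"vmax": fit.derived.vmax, "k_half": fit.derived.k_half,
                    "c_opt": (None if not fit.derived.has_optimum
                              else fit.derived.c_opt),
                    "has_optimum": fit.derived.has_optimum},
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "s_at_boundary": fit.s_at_boundary,
        "ci": {k: list(v) for k, v in fit.ci.items()},
        "n_boot_failed": fit.n_boot_failed,
        "boot_mode": fit.boot_mode,
        "seed": fit.seed,
    }


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write versioned outputs + manifest.

    Stages: (simulate) → process cultures → per-species fit + bootstrap →
    landscape grid → OA/OAE thresholds. Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "package_version": __version__,
                "seed": config.seed, "config": asdict(config),
                "stages": {}, "warnings": []}

    # --- stage: inputs ---
    if config.simulate:
        rng = np.random.default_rng(config.seed)
        culs, flus = [], []
        for name in config.simulate:
            prof = CANONICAL_PROFILES[name]
            c, f = simulate_experiment(prof, ExperimentDesign(),
                                       seed=int(rng.integers(0, 2**31 - 1)))
            culs.append(c)
            flus.append(f)
        cultures = pd.concat(culs, ignore_index=True)
        fluor = pd.concat(flus, ignore_index=True)
        cultures.to_csv(out / "cultures.csv", index=False)
        fluor.to_csv(out / "fluorescence.csv", index=False)
        manifest["stages"]["simulate"] = {"species": list(config.simulate),
                                          "n_cultures": len(cultures)}
    else:
        if not config.cultures_csv or not config.fluorescence_csv:
            raise ValueError(
                "config needs either 'simulate' profiles or both "
                "cultures_csv and fluorescence_csv")
        cultures = pd.read_csv(config.cultures_csv)
        fluor = pd.read_csv(config.fluorescence_csv)
        manifest["stages"]["inputs"] = {
            "cultures_csv": _hash(Path(config.cultures_csv)),
            "fluorescence_csv": _hash(Path(config.fluorescence_csv))}

    # --- stage: process ---
    table = process_cultures(cultures, fluor,
                             exclusion_threshold=config.exclusion_threshold)
    table.to_csv(out / "analysis_table.csv", index=False)
    n_excl = int(table["excluded"].sum())
    manifest["stages"]["process"] = {"n_cultures": len(table),
                                     "n_excluded": n_excl}
    log.info("processed %d cultures (%d excluded)", len(table), n_excl)

    # --- stage: fit per species ---
    fits: dict[str, FitResult] = {}
    for sp, grp in table[~table["excluded"]].groupby("species"):
        pts = np.column_stack([grp["mean_co2"], grp["growth_rate"]])
        model = (select_model(pts, seed=config.seed)
                 if config.model == "auto" else config.model)
        fit = fit_growth_model(pts, model, seed=config.seed)
        fit = bootstrap_ci(pts, fit, n_reps=config.boot_reps,
                           mode=config.boot_mode, seed=config.seed)
        fits[sp] = fit
        with open(out / f"fit_{sp}.json", "w") as fh:
            json.dump(fit_result_to_dict(fit), fh, indent=1)
    manifest["stages"]["fit"] = {
        sp: {"model": f.model_id, "r_squared": round(f.r_squared, 4),
             "n_boot_failed": f.n_boot_failed} for sp, f in fits.items()}

    # --- stage: landscape + thresholds ---
    grid = GridSpec(**config.grid)
    scenario = ScenarioSpec(**config.scenario) if config.scenario \
        else ScenarioSpec()
    thresholds = {}
    for sp, fit in fits.items():
        ls = predict_landscape(fit, grid, fraction=config.fraction)
        ls.table.to_csv(out / f"landscape_{sp}.csv", index=False)
        thr = {"oae": alkalinity_threshold(fit, scenario, config.fraction),
               "oa": oa_threshold(fit, config.fraction)}
        if fit.derived.has_optimum:
            (lo, hi), (hlo, hhi) = optimum_interval(fit, config.fraction)
            thr["optimum_co2"] = [lo, hi]
            thr["optimum_h_nmol"] = [hlo, hhi]
        thresholds[sp] = thr
    with open(out / "thresholds.json", "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION,
                   "thresholds": thresholds}, fh, indent=1, default=float)
    manifest["stages"]["landscape"] = {
        "grid_cells": len(grid.ta_values()) * len(grid.dic_values())}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
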