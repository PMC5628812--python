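"""End-to-end orchestration: simulate -> PDS -> TDI -> coupling -> maps.

A run is driven by a versioned YAML config (unknown keys are errors)
and writes every product — grids as ESRI ASCII, tables as CSV,
statistics as JSON — plus a manifest with content hashes so a rerun
under the same seed can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import EnvGrid, GridSpec, write_ascii_grid
from .pds import compute_pds
from .traits import (TraitRecord, aggregate_taxa, build_group_traits,
                     compute_tdi_table)
from .coupling import (bioenv, bioenv_permutation_test,
                       community_dissimilarity, fit_tdi_glm, predict_tdi_map,
                       spearman_tests)
from .simulate import SimConfig, simulate_environment, simulate_survey

__all__ = ["RunConfig", "analyze", "run_all", "DEMO_CONFIG"]

log = logging.getLogger("benthosens")

CONFIG_SCHEMA_VERSION = 1

#: Demo study conditions: a 32x32 grid, 8 survey years, 120 taxa,
#: ~300 hauls in total.
DEMO_CONFIG: dict = {
    "schema_version": CONFIG_SCHEMA_VERSION,
    "seed": 0,
    "out_dir": "benthosens_run",
    "grid": {"n_rows": 32, "n_cols": 32, "cell_size_deg": 0.03},
    "sim": {
        "n_years": 8,
        "n_stations_per_year": 38,
        "n_taxa": 120,
        "corr_len": 4.0,
        "env_effect": 1.0,
        "suppression_rate": 0.8,
        "noise_sd": 1.0,
        "rare_taxon_frac": 0.15,
    },
    "analysis": {
        "min_years": 6,
        "homogeneity_mode": "and",
        "log_transform": "log1p",
        "n_perm": 99,
        "max_subset": 3,
        "bioenv_vars": ["depth", "currents", "ta", "dist01", "sfg01"],
    },
}

_ALLOWED_KEYS = {
    "": {"schema_version", "seed", "out_dir", "grid", "sim", "analysis"},
    "grid": {"n_rows", "n_cols", "cell_size_deg", "origin_lon", "origin_lat"},
    "sim": {"n_years", "n_stations_per_year", "n_taxa", "corr_len",
            "env_effect", "suppression_rate", "suppression_severity",
            "noise_sd", "rare_taxon_frac", "first_year"},
    "analysis": {"min_years", "homogeneity_mode", "log_transform", "n_perm",
                 "max_subset", "bioenv_vars"},
}


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    grid: GridSpec
    sim: SimConfig
    min_years: int = 6
    homogeneity_mode: str = "and"
    log_transform: str = "log1p"
    n_perm: int = 99
    max_subset: int = 3
    bioenv_vars: list[str] = dc_field(
        default_factory=lambda: ["depth", "currents", "ta", "dist01", "sfg01"])

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, "")
        if raw.get("schema_version") != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version must be {CONFIG_SCHEMA_VERSION}")
        if "seed" not in raw:
            raise ValueError("seed is mandatory")
        for section in ("grid", "sim", "analysis"):
            _check_keys(raw.get(section, {}), section)
        grid = GridSpec(**{"n_rows": 32, "n_cols": 32,
                           **raw.get("grid", {})})
        sim = SimConfig(grid=grid, seed=int(raw["seed"]),
                        **raw.get("sim", {}))
        analysis = raw.get("analysis", {})
        return cls(seed=int(raw["seed"]),
                   out_dir=Path(raw.get("out_dir", "benthosens_run")),
                   grid=grid, sim=sim, **analysis)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_keys(raw: dict, section: str) -> None:
    unknown = set(raw) - _ALLOWED_KEYS[section]
    if unknown:
        where = section or "top level"
        raise ValueError(f"unknown config keys at {where}: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def _sample(grid: EnvGrid, rows, cols) -> np.ndarray:
    vals = np.where(grid.mask, np.nan, grid.values)
    return vals[rows, cols]


def analyze(cfg: RunConfig, run_bioenv: bool = True) -> dict:
    """Run simulate -> PDS -> TDI -> coupling in memory.

    Returns every stage product keyed by name plus per-stage timings;
    :func:`run_all` adds the file outputs and manifest. ``run_bioenv``
    can be switched off when only the TDI/GLM path is needed (the
    subset search dominates the run time).
    """
    stages: dict[str, float] = {}

    t = _stage("simulate")
    stack, sediment, abrasion, _ = simulate_environment(cfg.sim)
    catch, stations, trait_table, truth = simulate_survey(
        stack, abrasion, cfg.sim)
    stages["simulate"] = round(time.perf_counter() - t, 3)

    t = _stage("pds")
    pds_out = compute_pds(stack, sediment, stack.sst_monthly)
    pds = pds_out["pds"]
    stages["pds"] = round(time.perf_counter() - t, 3)

    t = _stage("tdi")
    if trait_table.empty:
        raise RuntimeError("traits_tdi stage: missing trait table")
    plan = aggregate_taxa(catch, trait_table[["taxon_id", "genus", "family",
                                              "order", "class", "division"]],
                          min_years=cfg.min_years)
    species_traits = {
        row.taxon_id: TraitRecord(
            taxon_id=row.taxon_id, position=row.position, feeding=row.feeding,
            motility=row.motility, size=row.size, fragility=row.fragility)
        for row in trait_table.itertuples()
    }
    group_traits = build_group_traits(plan, species_traits,
                                      mode=cfg.homogeneity_mode)
    tdi = compute_tdi_table(catch, plan, group_traits,
                            transform=cfg.log_transform)
    stages["tdi"] = round(time.perf_counter() - t, 3)

    t = _stage("coupling")
    st = stations.set_index("station_id")
    rows_idx = st["row"].to_numpy()
    cols_idx = st["col"].to_numpy()
    env_table = pd.DataFrame({
        "depth": _sample(stack["depth"], rows_idx, cols_idx),
        "currents": _sample(stack["currents"], rows_idx, cols_idx),
        "ta": _sample(pds_out["ta"], rows_idx, cols_idx),
        "dist01": _sample(pds.dist01, rows_idx, cols_idx),
        "sfg01": _sample(pds.sfg01, rows_idx, cols_idx),
        "risk": _sample(pds.risk, rows_idx, cols_idx),
        "abrasion": _sample(abrasion, rows_idx, cols_idx),
    }, index=st.index)

    be = be_p = None
    if run_bioenv:
        mapped = catch.assign(group=catch["taxon_id"].map(plan.assignments))
        mapped = mapped[mapped["group"].isin(group_traits)]
        comp = (mapped.assign(logb=np.log1p(mapped["biomass"]))
                .pivot_table(index="station_id", columns="group",
                             values="logb", aggfunc="sum", fill_value=0.0))
        comp = comp[comp.sum(axis=1) > 0]
        community = community_dissimilarity(comp)
        env_for_bioenv = env_table.loc[comp.index, cfg.bioenv_vars].dropna()
        community_sub = _subset_matrix(community, env_for_bioenv.index)
        be = bioenv(community_sub, env_for_bioenv,
                    max_subset_size=cfg.max_subset)
        be_p = bioenv_permutation_test(
            be, n_perm=cfg.n_perm, seed=np.random.default_rng(cfg.seed + 17))

    joint = tdi.join(env_table, how="inner").dropna(
        subset=["tdi", "risk", "abrasion"])
    joint = joint[joint["tdi"] > 0]
    rho, pval = spearman_tests(
        joint[["tdi", "risk", "dist01", "sfg01", "abrasion"]])
    fit = fit_tdi_glm(joint["tdi"], joint["risk"], joint["abrasion"])
    tdi_map = predict_tdi_map(fit, pds.risk, abrasion)
    stages["coupling"] = round(time.perf_counter() - t, 3)

    return {
        "stack": stack, "sediment": sediment, "abrasion": abrasion,
        "catch": catch, "stations": stations, "trait_table": trait_table,
        "truth": truth, "pds_out": pds_out, "pds": pds, "plan": plan,
        "group_traits": group_traits, "tdi": tdi, "env_table": env_table,
        "joint": joint, "spearman_rho": rho, "spearman_p": pval,
        "bioenv": be, "bioenv_p": be_p, "glm": fit, "tdi_map": tdi_map,
        "stages": stages,
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {
        "version": __version__,
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    res = analyze(cfg)
    manifest["stages"].update(res["stages"])
    pds = res["pds"]
    abrasion = res["abrasion"]
    catch, stations, trait_table = (res["catch"], res["stations"],
                                    res["trait_table"])
    tdi, rho, pval = res["tdi"], res["spearman_rho"], res["spearman_p"]
    be, be_p, fit, tdi_map = (res["bioenv"], res["bioenv_p"], res["glm"],
                              res["tdi_map"])

    t = _stage("write")
    grids = {
        "dist01.asc": pds.dist01,
        "sfg01.asc": pds.sfg01,
        "risk.asc": pds.risk,
        "abrasion.asc": abrasion,
        "tdi_predicted.asc": tdi_map,
    }
    for fname, grid in grids.items():
        write_ascii_grid(grid, out / fname)
    catch.to_csv(out / "catch.csv", index=False)
    stations.to_csv(out / "stations.csv", index=False)
    trait_table.to_csv(out / "traits.csv", index=False)
    tdi.to_csv(out / "tdi.csv")
    rho.to_csv(out / "spearman_rho.csv")
    pval.to_csv(out / "spearman_p.csv")
    with open(out / "bioenv.json", "w") as fh:
        json.dump({
            "best_subset": list(be.best_subset),
            "best_rho": be.best_rho,
            "p_value": be_p,
            "selection_frequency": be.selection_frequency,
            "top": [{"subset": list(s), "rho": r}
                    for s, r in be.ranking[:10]],
        }, fh, indent=2)
    with open(out / "glm.json", "w") as fh:
        json.dump({
            "response_transform": fit.response_transform,
            "params": fit.params.to_dict(),
            "bse": fit.bse.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "dropped_predictors": list(fit.dropped_predictors),
        }, fh, indent=2)
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["stages"]["write"] = round(time.perf_counter() - t, 3)
    manifest["total_seconds"] = round(time.perf_counter() - t0, 3)
    manifest["config"] = {
        "seed": cfg.seed, "min_years": cfg.min_years,
        "homogeneity_mode": cfg.homogeneity_mode,
        "log_transform": cfg.log_transform, "n_perm": cfg.n_perm,
        "max_subset": cfg.max_subset, "bioenv_vars": cfg.bioenv_vars,
        "grid": {"n_rows": cfg.grid.n_rows, "n_cols": cfg.grid.n_cols},
        "sim": {k: v for k, v in asdict(cfg.sim).items() if k != "grid"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete in %.1fs", manifest["total_seconds"])
    return manifest


def _subset_matrix(m, keep_labels) -> "object":
    from .coupling import DissimilarityMatrix
    keep = [str(k) for k in keep_labels]
    idx = [m.labels.index(k) for k in keep]
    return DissimilarityMatrix(labels=keep, d=m.d[np.ix_(idx, idx)])
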