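"""End-to-end pipeline: simulate/ingest -> filter -> segment -> summarise ->
regress -> report.

A single config (YAML or dict) drives all stages; one root seed feeds every
source of randomness, and the run manifest records config hash, file
checksums and stage counts so a bundle is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .burden import (
    distribution_grid,
    percentile_curves,
    prevalence_by_day,
    prevalence_by_month,
    strata_mean_difference,
    symptom_day_summary,
)
from .datamodel import (
    ALL_STRATA,
    DESCRIPTIVE_LEVELS,
    DESCRIPTIVE_REFERENCES,
    ObservationWindow,
)
from .diary_io import apply_inclusion, read_covariates, read_diary, validate_covariates, validate_diary
from .episodes import age_at_first_episode, duration_summary, episodes_per_child, segment_episodes
from .regression import rate_ratio_table
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def window_from_config(config: dict[str, Any]) -> ObservationWindow:
    w = config.get("window", {})
    return ObservationWindow(
        start_day=int(w.get("start_day", 0)),
        end_day=int(w.get("end_day", 729)),
        completeness_threshold=float(w.get("completeness_threshold", 0.98)),
    )


def simulation_config(config: dict[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from the pipeline config's ``simulate`` block."""
    block = dict(config.get("simulate", {}))
    block.setdefault("seed", int(config.get("seed", 0)))
    window = window_from_config(config)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown simulate option(s): {sorted(unknown)}")
    return SimulationConfig(window=window, **block)


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format="%.6g", **kwargs)


def build_table1(counts: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: level frequencies, mean episode counts, and Welch
    mean differences to each covariate's descriptive reference level."""
    frames = []
    n_total = len(covariates)
    for name, levels in DESCRIPTIVE_LEVELS.items():
        groups = covariates[name].astype(str).where(covariates[name].notna())
        tab = strata_mean_difference(counts, groups,
                                     reference=DESCRIPTIVE_REFERENCES[name],
                                     level_order=[l for l in levels
                                                  if l in set(groups.dropna())])
        tab.insert(0, "covariate", name)
        tab["pct"] = 100.0 * tab["n"] / n_total
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute every stage and write the machine-readable table bundle.

    Outputs: covariates.csv + diary.csv + truth_episodes.csv (when
    simulating), episodes.csv, orphan_days.csv, table1.csv (descriptives +
    mean differences), table2.csv (symptom-day burden grid), table3.csv
    (episode-count grid), table4.csv (rate ratios), percentiles.csv,
    prevalence_by_day.csv, prevalence_by_month.csv, manifest.json.
    Deterministic: identical config -> byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = window_from_config(config)
    missing_rule = config.get("missing_rule", "free")
    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "stages": {},
        "outputs": {},
    }

    # --- stage: acquire ---------------------------------------------------
    simulated = "simulate" in config
    if simulated:
        sim_cfg = simulation_config(config)
        covariates, diary, truth = simulate_cohort(sim_cfg)
        covariates_out = covariates.copy()
        covariates_out["birth_date"] = covariates_out["birth_date"].dt.strftime("%Y-%m-%d")
        _write(covariates_out, out / "covariates.csv", index=False)
        diary_out = diary.drop(columns="day_of_life").copy()
        diary_out["date"] = diary_out["date"].dt.strftime("%Y-%m-%d")
        _write(diary_out, out / "diary.csv", index=False)
        _write(truth, out / "truth_episodes.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_children": len(covariates),
            "n_diary_rows": len(diary),
            "n_truth_episodes": len(truth),
        }
    elif "inputs" in config:
        covariates = read_covariates(config["inputs"]["covariates"])
        diary = read_diary(config["inputs"]["diary"], covariates, window)
        manifest["inputs"] = {
            k: _checksum(Path(v)) for k, v in config["inputs"].items()}
    else:
        raise ValueError("config needs either a 'simulate' block or 'inputs' paths")

    # --- stage: inclusion filter -----------------------------------------
    included, excluded = apply_inclusion(diary, covariates, window)
    child_ids = sorted(included)
    diary = diary.loc[diary["child_id"].isin(included)].reset_index(drop=True)
    covariates = covariates.loc[child_ids]
    manifest["stages"]["inclusion"] = {
        "n_included": len(included),
        "n_excluded": len(excluded),
        "n_child_days": int(len(diary)),
    }
    logger.info("inclusion: %d included / %d excluded", len(included), len(excluded))

    # --- stage: segmentation ----------------------------------------------
    episodes, orphans = segment_episodes(diary, child_ids, window, missing_rule)
    _write(episodes, out / "episodes.csv", index=False)
    _write(orphans, out / "orphan_days.csv", index=False)
    manifest["stages"]["segment"] = {
        "n_episodes": int(len(episodes)),
        "n_orphan_days": int(len(orphans)),
        "missing_rule": missing_rule,
    }

    # --- stage: burden -----------------------------------------------------
    cohort = symptom_day_summary(diary, child_ids, window)
    _write(cohort.summary, out / "table2.csv", index_label="statistic")
    _write(percentile_curves(cohort.per_child), out / "percentiles.csv", index=False)
    _write(prevalence_by_day(diary, episodes, child_ids, window),
           out / "prevalence_by_day.csv", index=False)
    _write(prevalence_by_month(diary, episodes, covariates, child_ids, window),
           out / "prevalence_by_month.csv", index=False)
    manifest["stages"]["burden"] = {
        "n_child_days": cohort.n_child_days,
        "n_symptomatic_days": cohort.n_symptomatic_days,
        "fraction_symptomatic": round(cohort.fraction_symptomatic, 6),
    }

    # --- stage: episode summaries (tables 1 and 3) -------------------------
    counts_by_stratum = episodes_per_child(episodes, child_ids, ALL_STRATA)
    _write(distribution_grid(counts_by_stratum), out / "table3.csv",
           index_label="statistic")
    counts = counts_by_stratum["0-24 months"]
    _write(build_table1(counts, covariates), out / "table1.csv", index=False)
    first = age_at_first_episode(episodes, child_ids)
    manifest["stages"]["episodes"] = {
        "total_episodes": int(len(episodes)),
        "mean_per_child": round(float(counts.mean()), 4),
        "median_age_first_episode_days": (
            round(float(first.median()), 2) if first.notna().any() else None),
        "duration": {k: round(v, 4) for k, v in
                     duration_summary(episodes).items()},
    }

    # --- stage: regression --------------------------------------------------
    offset_days = None
    if config.get("offset_days"):
        offset_days = diary.groupby("child_id").size().reindex(child_ids)
    table4 = rate_ratio_table(counts, covariates, offset_days=offset_days)
    _write(table4, out / "table4.csv", index=False)
    manifest["stages"]["regression"] = {
        "n_adjusted": table4.attrs["n_adjusted"],
        "offset_days": bool(offset_days is not None),
    }

    # --- manifest ----------------------------------------------------------
    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _checksum(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
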