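"""End-to-end orchestration: data -> DHW -> BSI -> traits -> trade-offs.

A single :class:`RunConfig` (constructible from YAML) drives the whole
analysis; :func:`run_full_analysis` writes every stage's table plus a JSON
run summary and is a pure function of config + seed, so identical configs
give identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bleaching, data_io, synth, thermal, tradeoff, traits
from .errors import ConfigError
from .synth import CONTROL_TANKS, HEAT_TANKS, SyntheticConfig
from .tradeoff import BayesLMPrior

log = logging.getLogger("coraltrade")

INPUT_SCHEMAS = ("temperature", "health", "size", "dissection", "symbiont",
                 "polyp_density")


@dataclass
class RunConfig:
    """Everything one run needs: inputs (or a synth block) and settings."""

    output_dir: Path = Path("results/run")
    synth: SyntheticConfig | None = None
    input_paths: dict = field(default_factory=dict)   # schema -> path
    column_maps: dict = field(default_factory=dict)   # schema -> {canon: file}
    heat_tanks: tuple = HEAT_TANKS
    control_tanks: tuple = CONTROL_TANKS
    mmm: float | None = None            # satellite MMM when fitting baseline
    mmm_adj: float | None = None        # or a pre-adjusted baseline directly
    n_grid_levels: int = 21
    hotspot_rule: str = ">1"
    interpolation: str = "step"
    tolerance_average_axis: str = "grid"      # or "surveys"
    prior: BayesLMPrior = field(default_factory=BayesLMPrior)
    sensitivity: bool = True
    seed: int = 0

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if self.synth is None and not self.input_paths:
            raise ConfigError("config needs either a synth block or input paths")
        if self.tolerance_average_axis not in {"grid", "surveys"}:
            raise ConfigError("tolerance_average_axis must be 'grid' or 'surveys'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        synth_cfg = raw.pop("synth", None)
        prior_cfg = raw.pop("prior", None)
        kwargs = dict(raw)
        if synth_cfg is not None:
            kwargs["synth"] = SyntheticConfig(**synth_cfg)
        if prior_cfg is not None:
            kwargs["prior"] = BayesLMPrior(**prior_cfg)
        return cls(**kwargs)


def _load_inputs(config: RunConfig) -> dict:
    if config.synth is not None:
        cfg = config.synth
        if cfg.seed != config.seed:
            cfg = SyntheticConfig(**{**cfg.__dict__, "seed": config.seed})
        return synth.generate_dataset(cfg)
    data = {name: data_io.read_table(config.input_paths[name], name,
                                     config.column_maps.get(name))
            for name in INPUT_SCHEMAS}
    return data


def _survey_axis_trajectories(health: pd.DataFrame, heat_tanks) -> pd.DataFrame:
    """Colony BSI per survey timepoint (the non-default averaging axis)."""
    heat = health[health["tank_id"].isin(heat_tanks)].copy()
    order = {t: i for i, t in enumerate(sorted(heat["survey_time"].unique()))}
    heat["dhw_level"] = heat["survey_time"].map(order).astype(float)
    return bleaching.colony_trajectories(
        heat.rename(columns={"survey_time": "_t"}))


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage, write all outputs under ``config.output_dir``.

    Returns a dict with the stage tables and the JSON-serializable summary.
    """
    t0 = time.time()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def mark(stage):
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s done at %.2fs", stage, timings[stage])

    data = _load_inputs(config)
    for name in INPUT_SCHEMAS:
        data_io.validate_records(data[name], name)
        if len(data[name]):
            data_io.write_results(data[name], out / f"input_{name}.csv")
    if "truth" in data:
        data_io.write_results(data["truth"], out / "input_truth.csv")
    mark("data")

    # --- thermal stress ---------------------------------------------------
    if "stress" in data:          # synthetic mode reuses the generator's DHW
        stress = data["stress"]
        cal = data["calibration"]
        baseline = thermal.fit_baseline_adjustment(cal["satellite"],
                                                   cal["insitu"], cal["mmm"])
    else:
        if config.mmm_adj is not None:
            baseline = thermal.ClimatologyBaseline(
                mmm=config.mmm or config.mmm_adj, intercept=0.0, slope=1.0,
                mmm_adj=config.mmm_adj)
        else:
            raise ConfigError("file-based runs need mmm_adj (or baseline series)")
        stress = thermal.compute_dhw(data["temperature"], baseline,
                                     config.hotspot_rule)
    data_io.write_results(stress, out / "heat_stress.csv")
    grid = thermal.DhwGrid.from_stress(stress, config.n_grid_levels,
                                       list(config.heat_tanks))
    mark("thermal")

    # --- bleaching response -----------------------------------------------
    health, excluded = bleaching.apply_control_exclusion(
        data["health"], config.control_tanks)
    heat_records = health[health["tank_id"].isin(config.heat_tanks)]
    grid_cats = thermal.interpolate_health_at_grid(
        heat_records, stress, grid, method=config.interpolation)
    trajectories = bleaching.colony_trajectories(grid_cats)
    if config.tolerance_average_axis == "surveys":
        summaries = bleaching.summarize_tolerance(
            _survey_axis_trajectories(health, config.heat_tanks))
        summaries["critical_dhw"] = bleaching.summarize_tolerance(
            trajectories).set_index("colony_id").loc[
            summaries["colony_id"], "critical_dhw"].to_numpy()
    else:
        summaries = bleaching.summarize_tolerance(trajectories)
    data_io.write_results(trajectories, out / "bsi_trajectories.csv")
    data_io.write_results(summaries, out / "tolerance_summaries.csv")
    mark("bleaching")

    # --- colony traits ------------------------------------------------------
    growth = traits.corrected_growth(data["size"])
    initial = traits.initial_sizes(data["size"])
    fecundity = traits.fecundity_table(data["dissection"],
                                       data["polyp_density"], initial)
    if len(fecundity):
        trait_table = growth.merge(fecundity, on="colony_id", how="outer")
    else:
        trait_table = growth.copy()
    data_io.write_results(growth, out / "growth.csv")
    if len(fecundity):
        data_io.write_results(fecundity, out / "fecundity.csv")
    mark("traits")

    # --- trade-off inference ------------------------------------------------
    overall = tradeoff.overall_tradeoff_analysis(
        summaries, trait_table, prior=config.prior,
        sensitivity=config.sensitivity)
    data_io.write_results(overall, out / "tradeoff_overall.csv")

    progression = []
    for trait in tradeoff.OVERALL_TRAITS:
        if trait not in trait_table.columns:
            continue
        series = trait_table.set_index("colony_id")[trait]
        progression.append(tradeoff.slope_progression(
            trajectories, series, config.prior, trait_name=trait))
    progression = pd.concat(progression, ignore_index=True)
    data_io.write_results(progression, out / "tradeoff_progression.csv")

    symbiont_tests = tradeoff.symbiont_effect_test(trajectories,
                                                   data["symbiont"])
    if len(symbiont_tests):
        data_io.write_results(symbiont_tests, out / "symbiont_tests.csv")

    confounders = tradeoff.confounder_tests(
        summaries.merge(trait_table, on="colony_id", how="left")
        .merge(initial[["colony_id", "partial_mortality"]], on="colony_id",
               how="inner"),
        "partial_mortality",
        [c for c in ("average_bsi",) + tradeoff.OVERALL_TRAITS
         if c in trait_table.columns or c == "average_bsi"])
    if len(confounders):
        data_io.write_results(confounders, out / "confounder_tests.csv")

    try:
        pca = tradeoff.its2_pca(
            data["symbiont"],
            summaries.set_index("colony_id")["tolerance_category"])
        data_io.write_results(pca["scores"], out / "its2_pca_scores.csv")
    except Exception as exc:      # degenerate symbiont table is non-fatal
        log.warning("ITS2 PCA skipped: %s", exc)
        pca = None
    mark("tradeoff")

    finals = (stress[stress["tank_id"].isin(config.heat_tanks)]
              .sort_values("date").groupby("tank_id")["dhw_c_weeks"].last())
    summary = {
        "seed": config.seed,
        "n_colonies_scored": int(summaries["colony_id"].nunique()),
        "excluded_colonies": excluded,
        "final_dhw_per_tank": {k: round(float(v), 3) for k, v in finals.items()},
        "final_dhw_max": round(float(finals.max()), 3),
        "grid_max_dhw": round(float(grid.levels[-1]), 3),
        "mean_critical_dhw": round(float(summaries["critical_dhw"].mean()), 3),
        "mean_average_bsi": round(float(summaries["average_bsi"].mean()), 4),
        "p_positive": {
            f"{r.trait_name}[{r.variant}]": round(float(r.p_positive), 4)
            for r in overall.itertuples()},
        "stage_seconds": timings,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return {"summary": summary, "stress": stress, "grid": grid,
            "trajectories": trajectories, "summaries": summaries,
            "growth": growth, "fecundity": fecundity,
            "trait_table": trait_table, "overall": overall,
            "progression": progression, "symbiont_tests": symbiont_tests,
            "confounders": confounders, "pca": pca, "excluded": excluded}
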