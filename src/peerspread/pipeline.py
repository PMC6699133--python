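"""Configuration, logging and end-to-end pipeline wiring.

Stages: ``generate`` (synthetic cohort tables) -> ``metrics`` (networks,
centralities, class structure) -> ``simulate`` (all conditions on all
classes) -> ``evaluate`` (contrasts, ANOVA, moderation, correlations).
Each stage reads its inputs from the output directory, so a pipeline can be
resumed from any completed stage.  A manifest records every file written,
the configuration hash, the master seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .abm import SimConfig
from .cohort import CohortSpec, cohort_tables
from .evaluation import evaluate
from .interventions import default_conditions, prepare_classes, run_experiment
from .metrics import centrality_table, structure_table
from .network import networks_from_tables

__all__ = ["PipelineConfig", "load_config", "run_pipeline",
           "stage_generate", "stage_metrics", "stage_simulate", "stage_evaluate"]

log = logging.getLogger("peerspread")


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_classes: int = 26
    class_size: tuple[int, int] = (10, 30)
    density_range: tuple[float, float] = (0.46, 0.90)
    pal_mean: float = 1.50
    pal_sd: float = 0.55
    pal_min: float = 0.45
    pal_max: float = 4.27
    steps_mean: float = 10_505.0
    steps_sd: float = 5_730.0

    def to_spec(self, seed: int) -> CohortSpec:
        return CohortSpec(
            n_classes=self.n_classes,
            class_size_range=tuple(self.class_size),
            density_range=tuple(self.density_range),
            pal_mean=self.pal_mean, pal_sd=self.pal_sd,
            pal_min=self.pal_min, pal_max=self.pal_max,
            steps_mean=self.steps_mean, steps_sd=self.steps_sd,
            seed=seed,
        )


class AbmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    days: int = 365
    eta: float = 0.05
    lambda_env: float = 0.15
    threshold: float = 0.2
    pal_bounds: tuple[float, float] = (0.1, 4.27)
    pal_ref: float = 7.0

    def to_sim_config(self) -> SimConfig:
        return SimConfig(days=self.days, eta=self.eta,
                         lambda_env=self.lambda_env, threshold=self.threshold,
                         pal_bounds=tuple(self.pal_bounds), pal_ref=self.pal_ref)


class ConditionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fraction: float = 0.15
    boost: float = 0.17
    random_replicates: int = 100


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    abm: AbmConfig = Field(default_factory=AbmConfig)
    conditions: ConditionConfig = Field(default_factory=ConditionConfig)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_generate(config: PipelineConfig) -> list[str]:
    out = _out(config)
    spec = config.cohort.to_spec(config.seed)
    participants, nominations = cohort_tables(spec)
    files = []
    for name, df in [("participants.csv", participants), ("nominations.csv", nominations)]:
        path = out / name
        df.to_csv(path, index=False)
        files.append(str(path))
    log.info("generated %d participants in %d classes",
             len(participants), participants["class_id"].nunique())
    return files


def stage_metrics(config: PipelineConfig) -> list[str]:
    out = _out(config)
    participants = pd.read_csv(out / "participants.csv")
    nominations = pd.read_csv(out / "nominations.csv")
    networks = networks_from_tables(participants, nominations)
    files = []
    for name, df in [("class_structure.csv", structure_table(networks)),
                     ("centrality.csv", centrality_table(networks))]:
        path = out / name
        df.to_csv(path)
        files.append(str(path))
    log.info("computed structure for %d class networks", len(networks))
    return files


def stage_simulate(config: PipelineConfig) -> list[str]:
    out = _out(config)
    participants = pd.read_csv(out / "participants.csv")
    nominations = pd.read_csv(out / "nominations.csv")
    networks = networks_from_tables(participants, nominations)
    classes = prepare_classes(participants, networks)
    conds = default_conditions(config.conditions.fraction,
                               config.conditions.boost,
                               config.conditions.random_replicates)
    try:
        results, trajectories = run_experiment(
            classes, config.abm.to_sim_config(), conditions=conds,
            master_seed=config.seed, collect_trajectories=True)
    except Exception as err:  # pragma: no cover - diagnostic wrapper
        raise RuntimeError(f"simulate stage failed: {err}") from err
    path = out / "results.csv"
    results.to_csv(path, index=False)
    traj_path = out / "trajectories.csv"
    trajectories.to_csv(traj_path, index=False)
    log.info("simulated %d class x condition cells", len(results))
    return [str(path), str(traj_path)]


def stage_evaluate(config: PipelineConfig) -> list[str]:
    out = _out(config)
    results = pd.read_csv(out / "results.csv")
    structure = pd.read_csv(out / "class_structure.csv", index_col="class_id")
    n_classes = results["class_id"].nunique()
    if n_classes < 5:
        log.warning("only %d classes; evaluation will be underpowered", n_classes)
    report = evaluate(results, structure)
    report["meta"] = {"version": __version__, "seed": config.seed,
                      "config_hash": config.config_hash()}
    path = out / "evaluation_report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    txt = out / "evaluation_report.txt"
    with open(txt, "w") as fh:
        fh.write(_format_report(report))
    return [str(path), str(txt)]


def _format_report(report: dict) -> str:
    lines = ["Condition mean success rates (% change day 0 -> 364):"]
    for k, v in report["condition_means"].items():
        lines.append(f"  {k:12s} {v:8.3f}")
    lines.append("\nPlanned contrasts (Satterthwaite df):")
    for row in report["planned_contrasts"]["effects"]:
        lines.append(f"  {row['effect']:28s} est {row['estimate']:8.3f} "
                     f"se {row['se']:6.3f} df {row['df']:7.1f} "
                     f"t {row['t']:6.2f} p {row['p']:.4f}")
    a = report["rm_anova"]
    lines.append(f"\nRM-ANOVA: Mauchly W={a['mauchly_w']:.4f} (p={a['mauchly_p']:.4f}), "
                 f"HF epsilon={a['epsilon_hf']:.3f}, "
                 f"F({a['df1']:.2f},{a['df2']:.2f})={a['F']:.2f}, p={a['p']:.4f}")
    lines.append("\nModeration (standardized moderators):")
    for mod, fit in report["moderation"].items():
        main = next(r for r in fit["effects"] if r["effect"] == mod)
        lines.append(f"  {mod:28s} est {main['estimate']:8.3f} "
                     f"t {main['t']:6.2f} p {main['p']:.4f}"
                     + ("  [singular fit]" if fit["singular"] else ""))
    lines.append("\nCorrelations of success rate with class structure (r):")
    r = pd.DataFrame(report["structure_correlations"]["r"])
    lines.append(r.round(2).to_string())
    return "\n".join(lines) + "\n"


STAGES = {
    "generate": stage_generate,
    "metrics": stage_metrics,
    "simulate": stage_simulate,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the manifest."""
    logging.basicConfig(level=config.log_level)
    stages = stages or list(STAGES)
    out = _out(config)
    files: list[str] = []
    for name in stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        log.info("stage %s", name)
        files.extend(STAGES[name](config))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest_files = files + [str(out / "manifest.json")]
    missing = [f for f in manifest_files if not Path(f).exists()]
    if missing:  # pragma: no cover - defensive
        raise RuntimeError(f"manifest lists missing files: {missing}")
    return manifest
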