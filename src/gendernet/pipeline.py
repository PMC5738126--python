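"""End-to-end orchestration: generate -> load -> filter -> metrics ->
effects -> homophily -> impute -> predict, as one configured, seeded run.

Every stage output is a pure function of (inputs, config, seed); the run
directory receives each stage's artifact plus a manifest with the config,
derived seeds, and SHA-256 checksums, so a rerun with the same config
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_data import CHANNELS, CohortData, filter_active, read_cohort
from .effect_size import effect_size_table
from .gender_prediction import (
    MODEL_FAMILIES,
    assemble_features,
    default_grid,
    fit_forest_importance,
    tune_and_evaluate,
)
from .imputation import category_filter, default_category_map, knn_impute
from .mobility_metrics import mobility_indicator_table
from .network_metrics import call_duration_stats, network_indicator_table
from .permutation_null import homophily_test
from .synthetic_cohort import GeneratorConfig, generate, write_fixture

logger = logging.getLogger(__name__)

ALL_STAGES = ("generate", "metrics", "effects", "homophily", "impute", "predict")


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None  # read fixture instead of generating
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_active_weeks: int = 4
    n_subsamples: int = 1000
    homophily_window_weeks: int = 4
    homophily_channels: tuple[str, ...] = CHANNELS
    n_perm: int | str = "auto"  # 'auto' = min(2E, n_perm_cap)
    n_perm_cap: int = 2000
    k_neighbors: int = 7
    n_folds: int = 10
    n_estimators: int = 1000
    model_families: tuple[str, ...] = MODEL_FAMILIES


def pipeline_config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = raw.pop("generator", {})
    cfg = PipelineConfig(
        **{k: raw[k] for k in raw if k in PipelineConfig.__dataclass_fields__}
    )
    if gen_raw:
        cfg.generator = GeneratorConfig(
            **{k: gen_raw[k] for k in gen_raw if k in GeneratorConfig.__dataclass_fields__}
        )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log_stage(run_log: list, stage: str, status: str, **extra) -> None:
    event = {"stage": stage, "status": status, **extra}
    run_log.append(event)
    print(f"[gendernet] {stage}: {status} {extra if extra else ''}", file=sys.stderr)


def _resolve_n_perm(config: PipelineConfig, n_edges: int) -> int:
    if config.n_perm == "auto":
        return min(2 * n_edges, config.n_perm_cap)
    return int(config.n_perm)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the configured stages; returns the run directory.

    A stage failure aborts with the failing stage named; partial outputs are
    retained.  The manifest records config, seeds, versions, and per-output
    checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []
    outputs: dict[str, Path] = {}
    t0 = time.time()
    stage = "setup"
    try:
        stage = "generate"
        if config.input_dir is not None:
            data = read_cohort(
                Path(config.input_dir) / "participants.csv",
                Path(config.input_dir) / "interactions.csv",
                Path(config.input_dir) / "locations.csv",
                Path(config.input_dir) / "traits.csv",
            )
            _log_stage(run_log, stage, "loaded", source=str(config.input_dir))
        else:
            gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
            synth = generate(gen_cfg)
            if "generate" in config.stages:
                paths = write_fixture(synth, out / "fixture")
                outputs.update({f"fixture/{k}": v for k, v in paths.items()})
            data = synth.as_cohort_data()
            _log_stage(run_log, stage, "done", n_participants=len(data.cohort))

        cohort = filter_active(data.cohort, config.min_active_weeks)
        genders = pd.Series(cohort.genders())

        features = None
        if "metrics" in config.stages:
            stage = "metrics"
            mobility = mobility_indicator_table(cohort, data.locations)
            network = network_indicator_table(cohort, data.networks)
            features = pd.concat(
                [data.traits.reindex(cohort.ids), mobility, network], axis=1
            )
            features.index.name = "id"
            p = out / "features.csv"
            features.to_csv(p, float_format="%.10g")
            outputs["features"] = p
            call_events = data.networks["call"].events
            durations = call_duration_stats(call_events, cohort.genders())
            p = out / "call_durations.json"
            p.write_text(json.dumps(durations, indent=2, sort_keys=True) + "\n")
            outputs["call_durations"] = p
            _log_stage(run_log, stage, "done", n_features=features.shape[1])

        if "effects" in config.stages and features is not None:
            stage = "effects"
            effects = effect_size_table(
                features, genders, n_subsamples=config.n_subsamples, seed=config.seed + 1
            )
            p = out / "effects.json"
            p.write_text(
                json.dumps(
                    {k: v.to_dict() for k, v in effects.items()}, indent=2, sort_keys=True
                )
                + "\n"
            )
            outputs["effects"] = p
            _log_stage(run_log, stage, "done", n_indicators=len(effects))

        if "homophily" in config.stages:
            stage = "homophily"
            report = {}
            for i, channel in enumerate(config.homophily_channels):
                series = data.networks[channel]
                weeks = range(config.homophily_window_weeks)
                graph = series.aggregate(weeks).subgraph(cohort.ids)
                if graph.number_of_edges() == 0:
                    report[channel] = None
                    continue
                n_perm = _resolve_n_perm(config, graph.number_of_edges())
                ensembles = homophily_test(graph, n_perm=n_perm, seed=config.seed + 2 + i)
                report[channel] = {k: v.to_dict() for k, v in ensembles.items()}
            p = out / "homophily.json"
            p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            outputs["homophily"] = p
            _log_stage(run_log, stage, "done", channels=list(config.homophily_channels))

        complete = None
        if "impute" in config.stages and features is not None:
            stage = "impute"
            cat_map = default_category_map(features.columns)
            filtered = category_filter(features, cat_map)
            complete, fill_log = knn_impute(
                filtered, k=config.k_neighbors, return_log=True
            )
            p = out / "features_complete.csv"
            complete.to_csv(p, float_format="%.10g")
            outputs["features_complete"] = p
            p = out / "imputation_log.json"
            p.write_text(json.dumps(fill_log, indent=2) + "\n")
            outputs["imputation_log"] = p
            _log_stage(
                run_log, stage, "done",
                n_retained=len(complete), n_filled=len(fill_log),
            )

        if "predict" in config.stages and complete is not None:
            stage = "predict"
            y = (genders.reindex(complete.index) == "F").astype(int)
            grid = default_grid(n_estimators=config.n_estimators)
            report = tune_and_evaluate(
                complete, y, grid=grid, n_folds=config.n_folds,
                seed=config.seed + 10, families=tuple(config.model_families),
            )
            report.importance_ranking = fit_forest_importance(
                complete, y, seed=config.seed + 10, n_estimators=config.n_estimators
            )
            p = out / "report.json"
            p.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
            outputs["report"] = p
            _log_stage(run_log, stage, "done")
        elif "predict" not in config.stages:
            _log_stage(run_log, "predict", "skipped")
    except Exception:
        _log_stage(run_log, stage, "failed")
        (out / "run.log").write_text(
            "\n".join(json.dumps(e) for e in run_log) + "\n"
        )
        raise

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "stages": list(config.stages),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {k: _sha256(v) for k, v in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(json.dumps(e) for e in run_log) + "\n")
    return out
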