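"""End-to-end orchestration: thin -> background -> select -> cv -> fit ->
project -> summarize, from a single seeded configuration.

Each stage's parameters, derived seed, and input/output content hashes are
recorded in a run manifest, so a rerun with the same config is
seed-reproducible and any divergence is attributable to a stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_selection import select_features
from .grid_io import EnvStack
from .pseudo_absence import PseudoAbsenceConfig, assemble_training_set
from .spatial_cv import RFParams, cross_validate, make_folds
from .suitability import compare_scenarios, fit_final_model, project, summarize
from .thinning import DEFAULT_THINNING_DISTANCES_KM, thin

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_dataset", "run_pipeline"]

# deterministic per-stage seed offsets from the global seed
_STAGE_OFFSETS = {"thin": 1, "background": 2, "select": 3, "cv": 4, "fit": 5}


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis; one global seed drives every
    stochastic stage via fixed offsets."""

    thinning_distances_km: tuple = DEFAULT_THINNING_DISTANCES_KM
    thinning_iterations: int = 100
    model_distance_km: float | None = 7.0  # None = unthinned baseline
    pa_disk_fraction: float = 0.5
    pa_min_dist_km: float = 25.0
    pa_lat_threshold: float = 64.0
    pa_n_total: int | None = None  # None = one per presence (1:1 balance)
    correlation_threshold: float = 0.8
    cv_block_km: float = 100.0
    cv_folds: int = 13
    cv_repeats: int = 20
    low_threshold: float = 0.25
    high_threshold: float = 0.5
    rf_params: RFParams = field(default_factory=RFParams)
    seed: int = 0
    selected_vars: list[str] | None = None  # manual override of selection

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_OFFSETS[stage]) % (2**31)


def _hash(obj) -> str:
    if isinstance(obj, np.ndarray):
        payload = obj.tobytes()
    elif isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(index=False).encode()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_dataset(presences, stack: EnvStack, config: PipelineConfig | None = None) -> dict:
    """Run the post-thinning pipeline on one presence dataset.

    Stages: pseudo-absence assembly, feature selection (unless overridden),
    spatial-block CV, final fit, present-stack projection, summary.
    """
    config = config or PipelineConfig()
    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    pa_cfg = PseudoAbsenceConfig(
        n_total=config.pa_n_total,
        disk_fraction=config.pa_disk_fraction,
        min_dist_km=config.pa_min_dist_km,
        random_lat_threshold=config.pa_lat_threshold,
        seed=config.stage_seed("background"),
    )
    occ, features = assemble_training_set(presences, pa_cfg, stack)

    if config.selected_vars is not None:
        missing = [v for v in config.selected_vars if v not in features.columns]
        if missing:
            raise ValueError(f"manual selection references unknown variables: {missing}")
        selected, audit = list(config.selected_vars), {"selected": list(config.selected_vars), "rule": "manual_override"}
    else:
        selected, audit = select_features(
            features,
            occ.labels,
            threshold=config.correlation_threshold,
            rf_params=config.rf_params,
            seed=config.stage_seed("select"),
            points=occ.points,
            cv_block_km=config.cv_block_km,
        )

    folds = make_folds(
        occ.points,
        block_km=config.cv_block_km,
        k=config.cv_folds,
        repeats=config.cv_repeats,
        seed=config.stage_seed("cv"),
    )
    cv_report = cross_validate(
        features[selected], occ.labels, folds, rf_params=config.rf_params, seed=config.stage_seed("cv")
    )

    model = fit_final_model(features, occ.labels, selected, rf_params=config.rf_params, seed=config.stage_seed("fit"))
    smap = project(model, stack, scenario_tag="present")
    summary = summarize(smap, low=config.low_threshold, high=config.high_threshold, block_km=config.cv_block_km)
    return {
        "occurrences": occ,
        "features": features,
        "selected": selected,
        "audit": audit,
        "cv_report": cv_report,
        "model": model,
        "map": smap,
        "summary": summary,
    }


def run_pipeline(
    presences,
    stack: EnvStack,
    config: PipelineConfig | None = None,
    future_stacks: dict[str, EnvStack] | None = None,
) -> dict:
    """Full seeded run returning results plus a stage-by-stage manifest.

    ``model_distance_km`` selects the thinning preset used for the final
    model (None keeps the full dataset); all configured presets are thinned
    and reported so the retention trade-off is visible in the manifest.
    """
    config = config or PipelineConfig()
    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    manifest: list[dict] = []

    thinned: dict[float, np.ndarray] = {}
    for d in config.thinning_distances_km:
        res = thin(presences, d, iterations=config.thinning_iterations, seed=config.stage_seed("thin"))
        thinned[d] = presences[res.retained]
    if config.model_distance_km is None:
        model_points = presences
        chosen = "full"
    else:
        if config.model_distance_km not in thinned:
            res = thin(
                presences,
                config.model_distance_km,
                iterations=config.thinning_iterations,
                seed=config.stage_seed("thin"),
            )
            thinned[config.model_distance_km] = presences[res.retained]
        model_points = thinned[config.model_distance_km]
        chosen = config.model_distance_km
    manifest.append(
        {
            "stage": "thin",
            "seed": config.stage_seed("thin"),
            "params": {"distances_km": list(config.thinning_distances_km), "iterations": config.thinning_iterations},
            "input": _hash(presences),
            "output": {str(d): {"n": int(p.shape[0]), "hash": _hash(p)} for d, p in thinned.items()},
            "model_dataset": str(chosen),
        }
    )

    res = run_dataset(model_points, stack, config)

    manifest.append(
        {
            "stage": "background",
            "seed": config.stage_seed("background"),
            "params": {
                "disk_fraction": config.pa_disk_fraction,
                "min_dist_km": config.pa_min_dist_km,
                "lat_threshold": config.pa_lat_threshold,
                "n_total": config.pa_n_total,
            },
            "output": {"n_rows": len(res["occurrences"]), "hash": _hash(res["features"])},
        }
    )
    manifest.append(
        {
            "stage": "select",
            "seed": config.stage_seed("select"),
            "params": {"threshold": config.correlation_threshold},
            "output": {"selected": res["selected"]},
        }
    )
    manifest.append(
        {
            "stage": "cv",
            "seed": config.stage_seed("cv"),
            "params": {"block_km": config.cv_block_km, "k": config.cv_folds, "repeats": config.cv_repeats},
            "output": {"auc_mean": res["cv_report"].auc_mean, "auc_sd": res["cv_report"].auc_sd},
        }
    )
    manifest.append(
        {
            "stage": "fit",
            "seed": config.stage_seed("fit"),
            "params": {"rf": asdict(config.rf_params)},
            "output": {"variables": res["model"].variables},
        }
    )

    maps = [res["map"]]
    if future_stacks:
        for tag, fstack in future_stacks.items():
            maps.append(project(res["model"], fstack, scenario_tag=tag))
    manifest.append(
        {
            "stage": "project",
            "params": {"scenarios": [m.scenario for m in maps]},
            "output": {m.scenario: _hash(m.grid.values) for m in maps},
        }
    )

    table, diffs = compare_scenarios(
        maps, low=config.low_threshold, high=config.high_threshold, block_km=config.cv_block_km
    )
    manifest.append(
        {
            "stage": "summarize",
            "params": {"low": config.low_threshold, "high": config.high_threshold},
            "output": table.to_dict(orient="records"),
        }
    )

    res.update({"maps": maps, "scenario_table": table, "difference_maps": diffs, "manifest": manifest, "thinned": thinned})
    return res


def save_manifest(manifest: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
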