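"""End-to-end orchestration of the multi-model pipeline.

``run_pipeline`` executes: simulate → thin → select-vars → fit (HLCAm, LCAm,
Cm) → evaluate (incl. null models) → project (current everywhere; futures
for LCAm and Cm only — the baseline model's habitat layers have no future
analogue) → classify → prioritize → shift → threats → range-eval, persisting
every intermediate artifact plus a manifest (config hash, stage seeds,
version) into a run directory. Each stage is also callable on an existing
run directory, which is what the CLI subcommands do.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .ensemble import SDMModel, fit_sdm
from .grid import Raster
from .habitat import (
    apply_mask,
    area_report,
    disturbance_mask,
    range_shift,
    rank_priorities,
    reclassify,
)
from .io import read_stack, write_ascii_grid, write_geojson, write_stack
from .metrics import boyce_index, null_model_test
from .occurrences import OccurrenceSet, dedupe, load_occurrences, thin_occurrences
from .predictors import DEFAULT_VARIABLE_SETS
from .protected_areas import range_overlap, threat_assess
from .synth import (
    FutureScenario,
    LandscapeSpec,
    PolygonSet,
    TruthModel,
    make_future,
    make_landscape,
    make_polygons,
    sample_occurrences,
    true_suitability,
)
from .vif import elimination_trace_frame, vif_eliminate

logger = logging.getLogger(__name__)

MODEL_SET_NAMES = ("HLCAm", "LCAm", "Cm")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _seeded(cfg: RunConfig, stage: str) -> int:
    return cfg.stage_seed(stage)


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    s = cfg.synth
    spec = LandscapeSpec(
        seed=_seeded(cfg, "simulate"),
        n_rows=s.n_rows,
        n_cols=s.n_cols,
        cell_size_km=s.cell_size_km,
        n_climate_layers=s.n_climate_layers,
        autocorrelation_range_cells=s.autocorrelation_range_cells,
        landcover_classes=s.landcover_classes,
        river_count=s.river_count,
        road_count=s.road_count,
    )
    stack = make_landscape(spec)
    write_stack(stack, rundir / "stacks" / "current")
    for name, sc in cfg.scenarios.items():
        fut = make_future(
            stack,
            FutureScenario(
                name=name,
                offsets=sc.offsets,
                scales=sc.scales,
                landcover_conversion=sc.landcover_conversion,
            ),
            seed=_seeded(cfg, f"future:{name}"),
        )
        write_stack(fut, rundir / "stacks" / name)
    truth = TruthModel(
        active_predictors=tuple(s.active_predictors),
        coefficients=tuple(s.coefficients),
        intercept=s.intercept,
    )
    suit = true_suitability(stack, truth)
    write_ascii_grid(suit, rundir / "true_suitability.asc")
    occ = sample_occurrences(suit, s.n_occurrences, seed=_seeded(cfg, "occurrences"))
    occ.to_csv(rundir / "occurrences_raw.csv")
    for kind, count, fname in (
        ("protected_area", s.pa_count, "protected_areas.geojson"),
        ("zone", s.zone_count, "zones.geojson"),
        ("range_category", 3, "ranges.geojson"),
    ):
        polys = make_polygons(spec, kind, seed=_seeded(cfg, f"polygons:{kind}"), count=count)
        write_geojson(polys.geometries, rundir / fname, polys.properties)
    (rundir / "landscape_spec.json").write_text(
        json.dumps({k: getattr(spec, k) for k in spec.__dataclass_fields__}, indent=2)
    )


def stage_thin(cfg: RunConfig, rundir: Path) -> OccurrenceSet:
    occ = load_occurrences(rundir / "occurrences_raw.csv")
    occ = dedupe(occ)
    thinned = thin_occurrences(
        occ,
        min_dist_km=cfg.thinning.min_dist_km,
        n_restarts=cfg.thinning.n_restarts,
        seed=_seeded(cfg, "thin"),
        method=cfg.thinning.method,
    )
    thinned.to_csv(rundir / "occurrences_thinned.csv")
    return thinned


def stage_select_vars(cfg: RunConfig, rundir: Path) -> dict[str, list[str]]:
    """VIF-eliminate the continuous members of each variable set.

    VIF is computed on a seeded region-wide subsample of valid cells;
    categorical layers are excluded from VIF and passed through.
    """
    stack = read_stack(rundir / "stacks" / "current")
    sets = {name: list(v) for name, v in (cfg.variable_sets or DEFAULT_VARIABLE_SETS).items()}
    rng = np.random.default_rng(_seeded(cfg, "select-vars"))
    valid = np.flatnonzero(stack.mask.ravel())
    take = rng.choice(valid, size=min(cfg.vif.subsample, valid.size), replace=False)
    row, col = np.unravel_index(take, stack.grid.shape)
    selected = {}
    for set_name, members in sets.items():
        cont = [m for m in members if m not in stack.categorical]
        cat = [m for m in members if m in stack.categorical]
        frame = pd.DataFrame({m: stack[m][row, col] for m in cont})
        survivors, trace = vif_eliminate(frame, threshold=cfg.vif.threshold)
        elimination_trace_frame(trace).to_csv(
            rundir / f"vif_trace_{set_name}.csv", index=False
        )
        selected[set_name] = survivors + cat
    (rundir / "selected_variables.json").write_text(json.dumps(selected, indent=2))
    return selected


def save_model_bundle(model: SDMModel, directory: Path) -> None:
    """Documented bundle layout: weights.csv, metrics.csv, metadata.json,
    plus a pickle of the fitted model for downstream stages."""
    directory.mkdir(parents=True, exist_ok=True)
    ens = model.ensemble
    pd.DataFrame(ens.weights_, columns=["family", "replicate", "weight"]).to_csv(
        directory / "weights.csv", index=False
    )
    rows = []
    for family, fits in ens.replicates_.items():
        for f in fits:
            rows.append(
                {
                    "family": family,
                    "replicate": f.replicate_index,
                    "test_auc": f.test_metrics.auc,
                    "test_tss": f.test_metrics.tss,
                    "cv_auc": float(np.mean([m.auc for m in f.fold_metrics])),
                    "cv_tss": float(np.mean([m.tss for m in f.fold_metrics])),
                }
            )
    pd.DataFrame(rows).to_csv(directory / "metrics.csv", index=False)
    ens.family_summary_.to_csv(directory / "family_summary.csv", index=False)
    meta = {
        "name": model.name,
        "variables": model.variables,
        "included_families": ens.included_families_,
        "excluded_families": ens.excluded_families_,
        "version": __version__,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    with open(directory / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)


def load_model_bundle(directory: Path) -> SDMModel:
    with open(Path(directory) / "model.pkl", "rb") as fh:
        return pickle.load(fh)


def stage_fit(cfg: RunConfig, rundir: Path) -> dict[str, SDMModel]:
    stack = read_stack(rundir / "stacks" / "current")
    occ = load_occurrences(rundir / "occurrences_thinned.csv")
    selected = json.loads((rundir / "selected_variables.json").read_text())
    m = cfg.model
    models = {}
    for name in MODEL_SET_NAMES:
        model = fit_sdm(
            occ,
            stack,
            selected[name],
            name=name,
            families=tuple(m.families),
            n_replicates=m.n_replicates,
            n_folds=m.n_folds,
            train_fraction=m.train_fraction,
            inclusion_auc=m.inclusion_auc,
            weight_metric=m.weight_metric,
            exclusion_km=m.exclusion_km,
            n_background=m.n_background,
            learner_params=m.learner_params,
            seed=_seeded(cfg, f"fit:{name}"),
        )
        save_model_bundle(model, rundir / "models" / name)
        models[name] = model
    return models


def stage_evaluate(cfg: RunConfig, rundir: Path, models: dict[str, SDMModel]) -> pd.DataFrame:
    stack = read_stack(rundir / "stacks" / "current")
    occ = load_occurrences(rundir / "occurrences_thinned.csv")
    rows = []
    boyce_by_model = {}
    for name, model in models.items():
        surface = model.predict_surface(stack)
        pres_scores = surface.values[
            stack.grid.rowcol(occ.xy[:, 0], occ.xy[:, 1])
        ]
        pres_scores = pres_scores[np.isfinite(pres_scores)]
        bg_scores = surface.values[surface.mask]
        bi = boyce_index(pres_scores, bg_scores, n_bins=cfg.evaluation.boyce_bins)
        boyce_by_model[name] = bi
        fam = models[name].ensemble.family_summary_
        for _, r in fam.iterrows():
            rows.append(
                {
                    "model": name, "family": r["family"],
                    "cv_auc": r["cv_auc"], "cv_tss": r["cv_tss"],
                    "test_auc": r["test_auc"], "test_tss": r["test_tss"],
                    "included": r["included"], "ensemble_boyce": bi,
                }
            )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(rundir / "evaluation_metrics.csv", index=False)
    mean_bi = float(np.mean(list(boyce_by_model.values())))
    summary = {"boyce_by_model": boyce_by_model, "mean_boyce": mean_bi}

    nm = cfg.evaluation.null_model
    if nm.enabled:
        occ_n = len(occ)
        selected = json.loads((rundir / "selected_variables.json").read_text())
        null_rows = []
        for name, model in models.items():
            observed = float(
                np.mean([f.test_metrics.auc for fam in model.ensemble.replicates_.values() for f in fam])
            )

            def fit_eval(points, s, _vars=selected[name]):
                quick = fit_sdm(
                    points, stack, _vars,
                    families=tuple(nm.families),
                    n_replicates=nm.n_replicates,
                    n_folds=2, inclusion_auc=0.0,
                    exclusion_km=cfg.model.exclusion_km,
                    n_background=cfg.model.n_background,
                    seed=s,
                )
                return float(
                    np.mean(
                        [f.test_metrics.auc for fam in quick.ensemble.replicates_.values() for f in fam]
                    )
                )

            res = null_model_test(
                fit_eval, stack, occ_n,
                observed_auc=observed,
                n_iter=nm.n_iter,
                seed=_seeded(cfg, f"null:{name}"),
            )
            pd.DataFrame({"null_auc": res.null_aucs}).to_csv(
                rundir / f"null_distribution_{name}.csv", index=False
            )
            null_rows.append(
                {
                    "model": name, "observed_auc": res.observed_auc,
                    "null_mean_auc": float(res.null_aucs.mean()),
                    "ci95_upper": res.ci95_upper, "significant": res.significant,
                }
            )
        pd.DataFrame(null_rows).to_csv(rundir / "null_model_results.csv", index=False)
    (rundir / "evaluation_summary.json").write_text(json.dumps(summary, indent=2))
    return metrics


def stage_project(cfg: RunConfig, rundir: Path, models: dict[str, SDMModel]) -> dict:
    surfaces = {}
    current = read_stack(rundir / "stacks" / "current")
    (rundir / "surfaces").mkdir(exist_ok=True, parents=True)
    for name, model in models.items():
        surf = model.predict_surface(current)
        write_ascii_grid(surf, rundir / "surfaces" / f"{name}_current.asc")
        surfaces[(name, "current")] = surf
    for scen in cfg.scenarios:
        fut_stack = read_stack(rundir / "stacks" / scen)
        for name in cfg.model.project_future:
            surf = models[name].predict_surface(fut_stack)
            write_ascii_grid(surf, rundir / "surfaces" / f"{name}_{scen}.asc")
            surfaces[(name, scen)] = surf
    return surfaces


def stage_classify(cfg: RunConfig, rundir: Path, surfaces: dict) -> dict:
    classmaps = {}
    (rundir / "classes").mkdir(exist_ok=True, parents=True)
    bounds = tuple(cfg.classification.bounds)
    for (name, scen), surf in surfaces.items():
        cm = reclassify(surf, bounds=bounds, model=name, scenario=scen)
        classmaps[(name, scen)] = cm
        write_ascii_grid(
            Raster(cm.codes.astype(float), cm.grid, cm.mask, f"class_{name}_{scen}"),
            rundir / "classes" / f"{name}_{scen}.asc",
        )
    return classmaps


def stage_prioritize(cfg: RunConfig, rundir: Path, classmaps: dict):
    stack = read_stack(rundir / "stacks" / "current")
    dist = disturbance_mask(
        stack.raster("human_footprint"),
        stack.raster("human_modification"),
        threshold=cfg.priority.disturbance_threshold,
    )
    write_ascii_grid(dist, rundir / "disturbance_mask.asc")
    masked = {k: apply_mask(cm, dist) for k, cm in classmaps.items()}
    lcam_future = [masked[("LCAm", s)] for s in cfg.scenarios if ("LCAm", s) in masked]
    cm_future = [masked[("Cm", s)] for s in cfg.scenarios if ("Cm", s) in masked]
    priority = rank_priorities(
        masked[("HLCAm", "current")],
        masked[("LCAm", "current")],
        masked[("Cm", "current")],
        lcam_future,
        cm_future,
        dist,
        require_all_scenarios=cfg.priority.require_all_scenarios,
    )
    write_ascii_grid(
        Raster(priority.codes.astype(float), priority.grid, priority.mask, "priority"),
        rundir / "priority.asc",
    )
    counts = priority.counts()
    total = priority.grid.n_cells * priority.grid.cell_area_km2
    pd.DataFrame(
        [
            {
                "category": k,
                "area_km2": v * priority.grid.cell_area_km2,
                "percent": 100.0 * v * priority.grid.cell_area_km2 / total,
            }
            for k, v in counts.items()
        ]
    ).to_csv(rundir / "priority_areas.csv", index=False)
    return priority, masked


def stage_reports(cfg: RunConfig, rundir: Path, classmaps: dict) -> None:
    from .io import read_geojson

    zones_g, zones_p = read_geojson(rundir / "zones.geojson")
    zones = PolygonSet("zone", zones_g, zones_p)
    report = area_report(list(classmaps.values()))
    report.to_csv(rundir / "area_report.csv", index=False)
    zonal = area_report(list(classmaps.values()), zones=zones)
    zonal.to_csv(rundir / "area_report_zonal.csv", index=False)

    shifts = []
    for name in cfg.model.project_future:
        for scen in cfg.scenarios:
            if (name, scen) in classmaps:
                rs = range_shift(classmaps[(name, "current")], classmaps[(name, scen)])
                shifts.append(
                    {
                        "model": name, "scenario": scen,
                        "gain_km2": rs["gain_km2"], "loss_km2": rs["loss_km2"],
                        "stable_km2": rs["stable_km2"],
                        "shift_east_km": rs["centroid_shift_km"][0],
                        "shift_north_km": rs["centroid_shift_km"][1],
                    }
                )
    pd.DataFrame(shifts).to_csv(rundir / "range_shift.csv", index=False)


def stage_threats(cfg: RunConfig, rundir: Path) -> pd.DataFrame:
    from .io import read_geojson

    stack = read_stack(rundir / "stacks" / "current")
    pas_g, pas_p = read_geojson(rundir / "protected_areas.geojson")
    pas = PolygonSet("protected_area", pas_g, pas_p)
    t = cfg.threat
    report = threat_assess(
        pas,
        stack.raster("human_footprint"),
        stack.raster("human_modification"),
        stack.raster("dist_road") if "dist_road" in stack else None,
        esz_width_km=t.esz_width_km,
        disturbance_threshold=t.disturbance_threshold,
        road_km=t.road_km,
        flag_threshold=t.flag_threshold,
    )
    report.to_csv(rundir / "threat_report.csv", index=False)
    return report


def stage_range_eval(cfg: RunConfig, rundir: Path, classmaps: dict) -> pd.DataFrame:
    from .io import read_geojson

    ranges_g, ranges_p = read_geojson(rundir / "ranges.geojson")
    ranges = PolygonSet("range_category", ranges_g, ranges_p)
    table = range_overlap(classmaps[("HLCAm", "current")], ranges)
    table.to_csv(rundir / "range_overlap.csv", index=False)
    return table


# ---------------------------------------------------------------- driver


def config_hash(cfg: RunConfig) -> str:
    canon = yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, rundir: str | Path) -> Path:
    """Execute the full pipeline into ``rundir``; returns the run directory.

    Any stage failure aborts with the stage name; artifacts written by
    earlier stages are retained for inspection.
    """
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    stages = [
        ("simulate", lambda: stage_simulate(cfg, rundir)),
    ]
    state: dict = {}

    def _fit():
        state["models"] = stage_fit(cfg, rundir)

    def _evaluate():
        stage_evaluate(cfg, rundir, state["models"])

    def _project():
        state["surfaces"] = stage_project(cfg, rundir, state["models"])

    def _classify():
        state["classmaps"] = stage_classify(cfg, rundir, state["surfaces"])

    def _prioritize():
        state["priority"], state["masked"] = stage_prioritize(cfg, rundir, state["classmaps"])

    stages += [
        ("thin", lambda: stage_thin(cfg, rundir)),
        ("select-vars", lambda: stage_select_vars(cfg, rundir)),
        ("fit", _fit),
        ("evaluate", _evaluate),
        ("project", _project),
        ("classify", _classify),
        ("prioritize", _prioritize),
        ("reports", lambda: stage_reports(cfg, rundir, state["classmaps"])),
        ("threats", lambda: stage_threats(cfg, rundir)),
        ("range-eval", lambda: stage_range_eval(cfg, rundir, state["classmaps"])),
    ]
    manifest = {
        "config_hash": config_hash(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {},
        "stages_completed": [],
    }
    for stage_name, fn in stages:
        manifest["stage_seeds"][stage_name] = cfg.stage_seed(stage_name)
        logger.info("pipeline stage: %s", stage_name)
        try:
            fn()
        except Exception as exc:
            (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {stage_name!r} failed: {exc}") from exc
        manifest["stages_completed"].append(stage_name)
    (rundir / "config_used.yaml").write_text(
        yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True)
    )
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return rundir
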