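"""End-to-end orchestration of the planning study.

Stages mirror the study's modelling steps: generate (or load) the city,
summarise cases over census areas, fit the demand model, project
populations and future demand, build the OD matrix, optimise locations
for each requested fleet size and demand period, and evaluate/compare
scenarios.  One master seed fixes every stage; the manifest records
parameters and a content hash of every file written, so identical
configs produce identical manifests.

The demand model is fitted once on the current synthetic census and then
applied to each projected period's predictor table — prediction reuses
the fitted coefficients, only the inputs change.  Default sizes are the
scaled-down demo profile (200 areas, 12 sites, 300 generations); the
study-scale profile (2076 areas, 35 sites x 5 slots, 1500 generations)
is selected with ``profile: study``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, reference
from .cohort import CohortProjector, disaggregate_growth, predictor_table_from_age_sex
from .evaluate import calibrate_busy_prob, compare_scenarios
from .network import od_matrix
from .optimize import (AmbulanceLocationGA, LocationSet, brute_force_optimum,
                       candidate_slots_from_sites, fitness)
from .regression import StepwiseOLS, stepwise_select
from .synthetic import (admin_cohort_table, generate_city,
                        synthesize_prior_census)
from .network import count_points_in_polygons

logger = logging.getLogger(__name__)

ALL_STAGES = ["generate", "summarise", "fit", "project", "distances",
              "optimize", "evaluate"]

DEMO_PROFILE = dict(
    n_rows=15, n_cols=15, spacing_m=600.0, n_areas=200, total_pop=80_000,
    n_sites=12, slots_per_site=2, n_admin=8,
)
STUDY_PROFILE = dict(
    n_rows=40, n_cols=40, spacing_m=500.0,
    n_areas=reference.N_CENSUS_AREAS, total_pop=reference.TOTAL_POPULATION,
    n_sites=reference.N_SITES, slots_per_site=reference.SLOTS_PER_SITE,
    n_admin=reference.N_ADMIN_AREAS,
)

DEFAULT_CANDIDATES = ["pop_0_4", "pop_15_64", "pop_65_over", "pop_80_over",
                      "companies_5plus"]


def default_config(seed: int = 0, profile: str = "demo") -> dict:
    city = dict(DEMO_PROFILE if profile == "demo" else STUDY_PROFILE)
    return {
        "seed": seed,
        "profile": profile,
        "stages": list(ALL_STAGES),
        "synthetic_city": {**city, "scatter_points": True},
        "demand_regression": {
            "candidates": list(DEFAULT_CANDIDATES),
            "p_enter": 0.05, "p_remove": 0.10,
        },
        "cohort_projection": {"horizon": 2040},
        "distances": {"speed_kmh": 30.0},
        "grouping_ga": {
            "n_values": [4, 6] if profile == "demo" else [27],
            "generations": 300 if profile == "demo" else 1500,
            "population_size": 50 if profile == "demo" else 100,
            "periods": ["current", "horizon"],
        },
        "evaluation": {
            "target_rank1_share": reference.OBSERVED_RANK1_SHARE,
        },
    }


class PipelineStageError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the configured stages; return the run manifest."""
    if "seed" not in config:
        raise ValueError("config must set a seed")
    seed = int(config["seed"])
    stages = list(config.get("stages", ALL_STAGES))
    for st in stages:
        if st not in ALL_STAGES:
            raise ValueError(f"unknown stage {st!r}")
    outdir = Path(output_dir or config.get("output_dir", "emsloc_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ctx: dict = {}
    t0 = time.time()
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        tic = time.time()
        try:
            globals()[f"_stage_{stage}"](config, seed, ctx, outdir, written)
        except Exception as exc:  # partial outputs stay on disk
            raise PipelineStageError(stage, exc) from exc
        logger.info("stage %-10s done in %.1fs", stage, time.time() - tic)
    manifest = {
        "config": config,
        "seed": seed,
        "stages_run": stages,
        "elapsed_s": round(time.time() - t0, 2),
        "files": {str(p.relative_to(outdir)): _sha256(p)
                  for p in sorted(written)},
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _write(written, path, fn):
    fn(path)
    written.append(Path(path))


def _stage_generate(config, seed, ctx, outdir, written):
    params = dict(config.get("synthetic_city", {}))
    params.pop("profile", None)
    city = generate_city(seed=seed, **params)
    ctx["city"] = city
    _write(written, outdir / "areas.geojson",
           lambda p: io.write_areas_geojson(city.areas, p))
    _write(written, outdir / "demographics.csv",
           lambda p: city.areas.table.to_csv(p))
    _write(written, outdir / "age_sex.csv",
           lambda p: city.areas.age_sex.to_csv(p, index=False))
    _write(written, outdir / "sites.csv", lambda p: city.sites.to_csv(p))
    _write(written, outdir / "nodes.csv",
           lambda p: io.write_graph_csv(city.graph, p, outdir / "edges.csv"))
    written.append(outdir / "edges.csv")
    if city.case_points is not None:
        _write(written, outdir / "case_points.csv",
               lambda p: city.case_points.to_csv(p))


def _stage_summarise(config, seed, ctx, outdir, written):
    city = ctx["city"]
    if city.case_points is None:
        ctx["case_counts"] = city.areas.table["observed_cases"]
        return
    counts, unassigned = count_points_in_polygons(
        city.case_points, city.areas.polygons)
    if unassigned:
        logger.warning("%d case points outside all polygons", unassigned)
    ctx["case_counts"] = counts
    _write(written, outdir / "case_counts.csv", lambda p: counts.to_csv(p))


def _stage_fit(config, seed, ctx, outdir, written):
    city = ctx["city"]
    rc = config.get("demand_regression", {})
    model = stepwise_select(
        city.areas.table, rc.get("candidates", DEFAULT_CANDIDATES),
        ctx.get("case_counts", city.areas.table["observed_cases"]).to_numpy(),
        p_enter=rc.get("p_enter", 0.05), p_remove=rc.get("p_remove", 0.10))
    ctx["model"] = model
    _write(written, outdir / "demand_model.json", model.to_json)


def _stage_project(config, seed, ctx, outdir, written):
    city = ctx["city"]
    cc = config.get("cohort_projection", {})
    pop_2005 = admin_cohort_table(city.areas, period=2005)
    pop_2000 = synthesize_prior_census(pop_2005, seed=seed)
    proj = CohortProjector(
        total_fertility_rate=cc.get("tfr", reference.TOTAL_FERTILITY_RATE),
        horizon=cc.get("horizon", 2040),
    ).fit(pop_2000, pop_2005)
    periods = proj.project()
    ctx["projection"] = periods
    per_area = disaggregate_growth(
        periods, pop_2005, city.areas.age_sex, city.areas.table["admin_id"])
    model = ctx.get("model")
    rows, demand = [], {}
    for period, age_sex in per_area.items():
        table = predictor_table_from_age_sex(
            age_sex, city.areas.table["companies_5plus"],
            cc.get("company_growth", 1.0))
        if model is not None:
            pred = model.predict(table, clip_negative=True)
        else:
            pred = city.model.predict(table, clip_negative=True)
        demand[period] = pd.Series(pred, index=table.index,
                                   name="predicted_cases")
        for aid, v in demand[period].items():
            rows.append((period, aid, v))
    ctx["future_demand"] = demand
    out = pd.DataFrame(rows, columns=["period", "area_id",
                                      "predicted_cases"])
    _write(written, outdir / "future_demand.csv",
           lambda p: out.to_csv(p, index=False))
    totals = out.groupby("period")["predicted_cases"].sum().reset_index()
    _write(written, outdir / "demand_totals.csv",
           lambda p: totals.to_csv(p, index=False))


def _stage_distances(config, seed, ctx, outdir, written):
    city = ctx["city"]
    origins = city.areas.table.rename(
        columns={"centroid_x": "x", "centroid_y": "y"})[["x", "y"]]
    od = od_matrix(city.graph, origins, city.sites[["x", "y"]])
    ctx["od"] = od
    _write(written, outdir / "od_dense.csv",
           lambda p: io.write_od_dense(od, p))
    _write(written, outdir / "od_long.csv",
           lambda p: io.write_od_long(od, p))


def _demand_series(ctx, period):
    city = ctx["city"]
    if period == "current":
        return city.areas.table["observed_cases"]
    demand = ctx.get("future_demand", {})
    if period == "horizon":
        if not demand:
            return city.areas.table["observed_cases"]
        period = max(demand)
    return demand[period]


def _stage_optimize(config, seed, ctx, outdir, written):
    city = ctx["city"]
    od = ctx["od"]
    gc = config.get("grouping_ga", {})
    slots = candidate_slots_from_sites(city.sites)
    results = {}
    for period in gc.get("periods", ["current"]):
        w = _demand_series(ctx, period)
        for n in gc.get("n_values", [4]):
            ga = AmbulanceLocationGA(
                n=int(n),
                population_size=gc.get("population_size", 100),
                generations=gc.get("generations", 1500),
                crossover_rate=gc.get("crossover_rate", 0.9),
                mutation_rate=gc.get("mutation_rate", 0.05),
                early_stop=gc.get("early_stop"),
                random_state=seed + int(n),
            ).fit(od, w, slots)
            results[f"{period}_n{n}"] = {
                "period": period, "n": int(n),
                "slots": list(ga.best_set_.slots),
                "sites": list(ga.best_set_.sites),
                "best_fitness_person_m": ga.best_fitness_,
                "generations": len(ga.history_) - 1,
                "evaluations": ga.n_evaluations_,
            }
    ctx["optimized"] = results
    _write(written, outdir / "optimized_locations.json",
           lambda p: io.write_json(results, p))


def _stage_evaluate(config, seed, ctx, outdir, written):
    city = ctx["city"]
    od = ctx["od"]
    ec = config.get("evaluation", {})
    busy = ec.get("busy_prob")
    if busy is None:
        busy = calibrate_busy_prob(
            ec.get("target_rank1_share", reference.OBSERVED_RANK1_SHARE))
    results = ctx.get("optimized", {})
    rng = np.random.default_rng(seed)
    reports = {}
    for key, res in results.items():
        n = res["n"]
        current_sites = ec.get("current_sites")
        if current_sites is None:
            current_sites = sorted(
                rng.choice(od.columns.to_numpy(), size=n, replace=False))
        s_cur = LocationSet.from_sites(current_sites)
        s_opt = LocationSet(tuple((int(a), int(b)) for a, b in res["slots"]))
        w = _demand_series(ctx, res["period"])
        reports[key] = compare_scenarios(
            s_cur, s_opt, w.round().astype(int), od, w,
            busy_prob=busy, seed=seed,
            speed_kmh=config.get("distances", {}).get("speed_kmh", 30.0))
        reports[key]["current_sites"] = [int(x) for x in current_sites]
    ctx["reports"] = reports
    _write(written, outdir / "evaluation.json",
           lambda p: io.write_json(reports, p))


def sweep_n(od, weights, candidate_slots, n_values, *, oracle: bool = False,
            seed: int = 0, **ga_kwargs) -> pd.DataFrame:
    """Best fitness per fleet size n; flags non-monotone GA shortfalls."""
    rows = []
    for n in n_values:
        if oracle:
            _, f = brute_force_optimum(od, weights, int(n))
        else:
            res = AmbulanceLocationGA(n=int(n), random_state=seed + int(n),
                                      **ga_kwargs).fit(
                od, weights, candidate_slots)
            f = res.best_fitness_
        rows.append((int(n), float(f)))
    out = pd.DataFrame(rows, columns=["n", "best_fitness"])
    out["monotone"] = out["best_fitness"].diff().fillna(0.0) <= 1e-9
    for _, r in out[~out["monotone"]].iterrows():
        logger.warning("fitness increased at n=%d: GA shortfall", r["n"])
    return out
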