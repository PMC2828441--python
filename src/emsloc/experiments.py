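"""Replication studies: simulations that re-derive the published figures.

These helpers run the package end to end under the study conditions and
summarise the outcomes that can be checked against published values:

* parameter recovery — generate study-scale synthetic cities (2076
  census areas, population 814,000) from the published demand model with
  noise calibrated to its reported fit, refit by stepwise OLS, and
  average the recovered coefficients and R-squared across seeds;
* GA-versus-oracle — solve many small seeded p-median instances with
  both the grouping GA and exhaustive enumeration and count exact hits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference
from .optimize import brute_force_optimum, evolve
from .regression import stepwise_select
from .synthetic import generate_city

TRUE_COEFFICIENTS = reference.NIIGATA_MODEL_COEFFICIENTS
CANDIDATE_PREDICTORS = ["pop_0_4", "pop_15_64", "pop_65_over",
                        "pop_80_over", "companies_5plus"]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def parameter_recovery(n_seeds: int = 20, seed: int = 0,
                       n_areas: int = reference.N_CENSUS_AREAS,
                       total_pop: int = reference.TOTAL_POPULATION,
                       target_r2: float = reference.NIIGATA_MODEL_R_SQUARED,
                       ) -> pd.DataFrame:
    """Per-seed stepwise-OLS refits on model-generated synthetic cities.

    Returns one row per seed with the recovered coefficient for each
    candidate predictor (NaN where not selected) and the refit R-squared.
    """
    rows = []
    for s in _spawn_seeds(seed, n_seeds):
        city = generate_city(seed=s, n_areas=n_areas, total_pop=total_pop,
                             target_r2=target_r2)
        tab = city.areas.table
        m = stepwise_select(tab, CANDIDATE_PREDICTORS,
                            tab["observed_cases"].to_numpy())
        coefs = m.coefficients()
        rows.append({c: coefs.get(c, np.nan) for c in CANDIDATE_PREDICTORS}
                    | {"r_squared": m.rsquared_, "seed": s})
    return pd.DataFrame(rows)


def recovery_summary(runs: pd.DataFrame) -> dict:
    """Mean, simulation SE and selection count per predictor, plus R2."""
    out = {}
    for c in CANDIDATE_PREDICTORS:
        vals = runs[c].dropna()
        out[c] = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sim_se": (float(vals.std(ddof=1) / np.sqrt(len(vals)))
                       if len(vals) > 1 else float("nan")),
            "n_selected": int(len(vals)),
        }
    out["r_squared"] = {"mean": float(runs["r_squared"].mean()),
                        "sim_se": float(runs["r_squared"].std(ddof=1)
                                        / np.sqrt(len(runs)))}
    return out


def ga_oracle_study(n_instances: int = 100, seed: int = 0,
                    n_areas: int = 30, n_sites: int = 10, n: int = 3,
                    population_size: int = 30, generations: int = 40,
                    mutation_rate: float = 0.1) -> dict:
    """Count GA hits of the exact optimum on small random instances.

    Each instance has C(n_sites, n) enumerable subsets (120 by default,
    under the 500-subset tractability cap); the GA must also never beat
    the all-sites lower bound.
    """
    hits, below_bound = 0, 0
    for s in _spawn_seeds(seed, n_instances):
        rng = np.random.default_rng(s)
        od = pd.DataFrame(rng.uniform(100, 10_000, (n_areas, n_sites)),
                          columns=pd.Index(range(n_sites), name="site_id"))
        w = rng.integers(0, 20, n_areas).astype(float)
        _, best_f = brute_force_optimum(od, w, n)
        res = evolve(od, w, [(c, 0) for c in od.columns], n=n,
                     population_size=population_size,
                     generations=generations, mutation_rate=mutation_rate,
                     seed=s)
        bound = float(w @ od.to_numpy().min(axis=1))
        if res.best_fitness < bound - 1e-9:
            below_bound += 1
        if abs(res.best_fitness - best_f) < 1e-9:
            hits += 1
    return {"hits": hits, "n_instances": n_instances,
            "below_bound": below_bound}
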