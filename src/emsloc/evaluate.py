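"""Evaluation of a chosen set of ambulance locations.

Given a location set, an OD matrix and per-area case weights, this
module derives the ambulance catchments (each census area served by its
nearest chosen site), the per-site "busyness" index (catchment
person-distance, the quantity that sizes stations on demand maps), and a
simulated deployment record per case under a simple availability model:
each ambulance unit is independently busy with probability
``busy_prob``, and the nearest available unit responds ("nearest
available ambulance" dispatch).  Under that model the share of cases
served by their rank-1 unit is ``1 - busy_prob`` (exactly, up to the
truncation that the last unit always responds), so the observed rank-1
share — 67.8% in the study system — calibrates ``busy_prob`` directly.

Scenario comparisons (current vs optimised locations) are paired: the
same cases and the same busy-draw stream are applied to both scenarios
(common random numbers), so deltas carry no Monte-Carlo noise from
differing draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .network import DEFAULT_SPEED_KMH, distance_to_time
from .optimize import LocationSet, _check_weights, _site_columns, fitness

__all__ = [
    "Catchment",
    "assign_catchments",
    "busyness_index",
    "simulate_response",
    "summarize",
    "compare_scenarios",
    "calibrate_busy_prob",
]


@dataclass
class Catchment:
    site_id: int
    area_ids: list
    case_count: float
    person_distance: float


def assign_catchments(s: LocationSet, od: pd.DataFrame,
                      weights) -> list[Catchment]:
    """Assign every area to its nearest chosen site (ties: lowest id).

    The catchment person-distances decompose the location set's fitness
    exactly: their sum equals ``fitness(s, od, weights)`` bit-for-bit.
    """
    if s.n == 0:
        raise ParameterError("empty location set")
    cols = _site_columns(od)
    w = _check_weights(od, weights)
    sites = s.sites
    D = od.to_numpy()[:, [cols[x] for x in sites]]
    nearest = D.argmin(axis=1)
    dmin = D[np.arange(len(D)), nearest]
    contrib = w * dmin
    out = []
    for j, site in enumerate(sites):
        mask = nearest == j
        out.append(Catchment(
            site_id=site,
            area_ids=list(od.index[mask]),
            case_count=float(w[mask].sum()),
            person_distance=float(contrib[mask].sum()),
        ))
    return out


def busyness_index(catchments: list[Catchment]) -> pd.DataFrame:
    """Per-site person-distance and case count (the demand-map quantity)."""
    return pd.DataFrame(
        {"person_distance": [c.person_distance for c in catchments],
         "case_count": [c.case_count for c in catchments]},
        index=pd.Index([c.site_id for c in catchments], name="site_id"),
    )


# ---------------------------------------------------------------------------
# deployment simulation

def _unit_tables(s: LocationSet, od: pd.DataFrame):
    """Per-area unit ranking: site order by distance, expanded by slots.

    Returns (rank_dist, rank_site): arrays of shape (n_areas, n_units)
    giving, for each area, the distance and site of the unit at each
    deployment rank.  Duplicate slots at one site occupy consecutive
    ranks at the same distance.
    """
    cols = _site_columns(od)
    sites = s.sites
    slots_per = {x: sum(1 for sid, _ in s.slots if sid == x) for x in sites}
    D = od.to_numpy()[:, [cols[x] for x in sites]]
    order = np.argsort(D, axis=1, kind="stable")  # ties: lowest site id
    n_units = len(s.slots)
    rank_dist = np.empty((len(D), n_units))
    rank_site = np.empty((len(D), n_units), dtype=int)
    for i in range(len(D)):
        k = 0
        for j in order[i]:
            site = sites[j]
            for _ in range(slots_per[site]):
                rank_dist[i, k] = D[i, j]
                rank_site[i, k] = site
                k += 1
    return rank_dist, rank_site


def _respond(case_areas: np.ndarray, rank_dist, rank_site,
             uniforms: np.ndarray, busy_prob: float,
             speed_kmh: float) -> pd.DataFrame:
    free = uniforms >= busy_prob  # one draw per case x rank
    n_units = rank_dist.shape[1]
    first_free = np.where(free.any(axis=1), free.argmax(axis=1),
                          n_units - 1)  # last unit always responds
    dist = rank_dist[case_areas, first_free]
    site = rank_site[case_areas, first_free]
    return pd.DataFrame({
        "area_idx": case_areas,
        "responding_rank": first_free + 1,
        "site_id": site,
        "response_distance_m": dist,
        "response_time_s": distance_to_time(dist, speed_kmh),
    })


def simulate_response(cases, s: LocationSet, od: pd.DataFrame,
                      busy_prob: float = 0.0, seed: int = 0,
                      speed_kmh: float = DEFAULT_SPEED_KMH) -> pd.DataFrame:
    """Simulate which unit responds to each case.

    ``cases`` is a DataFrame with an ``area_id`` column (each case
    inherits its census area's OD row) or a per-area weight Series whose
    counts are expanded into cases.  Units are ranked per area by
    distance; each unit is independently busy with probability
    ``busy_prob``; the first free unit responds, the last unit
    unconditionally.
    """
    if not (0 <= busy_prob < 1):
        raise ParameterError("busy_prob must be in [0, 1)")
    if s.n == 0:
        raise ParameterError("empty location set")
    area_pos = {a: i for i, a in enumerate(od.index)}
    if isinstance(cases, pd.DataFrame):
        case_areas = np.array([area_pos[a] for a in cases["area_id"]])
    else:
        w = _check_weights(od, cases)
        case_areas = np.repeat(np.arange(len(od)), w.astype(int))
    rank_dist, rank_site = _unit_tables(s, od)
    rng = np.random.default_rng(seed)
    uniforms = rng.random((len(case_areas), len(s.slots)))
    rec = _respond(case_areas, rank_dist, rank_site, uniforms, busy_prob,
                   speed_kmh)
    rec.insert(0, "area_id", np.asarray(od.index)[rec.pop("area_idx")])
    rec.index.name = "case_id"
    return rec


def summarize(records: pd.DataFrame) -> dict:
    """Mean response time, rank-1 share and the deployment-rank histogram."""
    if len(records) == 0:
        raise ParameterError("no deployment records to summarise")
    ranks = records["responding_rank"]
    hist = ranks.value_counts().sort_index()
    return {
        "n_cases": int(len(records)),
        "mean_response_time_s": float(records["response_time_s"].mean()),
        "mean_response_distance_m": float(
            records["response_distance_m"].mean()),
        "pct_rank1": float(100.0 * (ranks == 1).mean()),
        "rank_histogram": {int(k): int(v) for k, v in hist.items()},
    }


def calibrate_busy_prob(target_rank1_share: float) -> float:
    """Busy probability whose rank-1 deployment share hits the target.

    Under independent unit availability the rank-1 unit responds iff it
    is free, so ``busy_prob = 1 - share`` (share as a fraction).
    """
    if not (0 < target_rank1_share <= 1):
        raise ParameterError("target share must be in (0, 1]")
    return 1.0 - target_rank1_share


def compare_scenarios(s_current: LocationSet, s_optimal: LocationSet,
                      cases, od: pd.DataFrame, weights,
                      busy_prob: float = 0.0, seed: int = 0,
                      speed_kmh: float = DEFAULT_SPEED_KMH) -> dict:
    """Paired current-vs-optimised evaluation on the same cases.

    Both scenarios see the same case list and the same busy-draw stream
    (common random numbers).  Reports per-scenario summaries under the
    busy model and under full availability (every case served by its
    nearest unit), the per-site busyness tables, and the deltas
    (optimal minus current).
    """
    area_pos = {a: i for i, a in enumerate(od.index)}
    if isinstance(cases, pd.DataFrame):
        case_areas = np.array([area_pos[a] for a in cases["area_id"]])
    else:
        w = _check_weights(od, cases)
        case_areas = np.repeat(np.arange(len(od)), w.astype(int))
    rng = np.random.default_rng(seed)
    max_units = max(len(s_current.slots), len(s_optimal.slots))
    uniforms = rng.random((len(case_areas), max_units))

    def run(s: LocationSet, busy: float) -> dict:
        rd, rs = _unit_tables(s, od)
        rec = _respond(case_areas, rd, rs, uniforms[:, : len(s.slots)],
                       busy, speed_kmh)
        return summarize(rec)

    out = {}
    for name, s in (("current", s_current), ("optimal", s_optimal)):
        catch = assign_catchments(s, od, weights)
        out[name] = {
            "simulated": run(s, busy_prob),
            "full_availability": run(s, 0.0),
            "fitness_person_m": fitness(s, od, weights),
            "busyness": busyness_index(catch).reset_index().to_dict(
                orient="list"),
        }
    out["delta"] = {
        "mean_response_time_s": (
            out["optimal"]["simulated"]["mean_response_time_s"]
            - out["current"]["simulated"]["mean_response_time_s"]),
        "pct_rank1": (out["optimal"]["simulated"]["pct_rank1"]
                      - out["current"]["simulated"]["pct_rank1"]),
        "fitness_person_m": (out["optimal"]["fitness_person_m"]
                             - out["current"]["fitness_person_m"]),
        "mean_nearest_time_s": (
            out["optimal"]["full_availability"]["mean_response_time_s"]
            - out["current"]["full_availability"]["mean_response_time_s"]),
    }
    out["busy_prob"] = busy_prob
    out["speed_kmh"] = speed_kmh
    return out
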