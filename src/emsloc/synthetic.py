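"""Seeded synthetic cities with the statistical structure of the study area.

The real inputs — EMS dispatch records, Japanese census small-area tables
and a commercial road network — are confidential, so every analysis in
this package runs on synthetic cities that reproduce their structure at
the study's scale: a connected road lattice, ~2076 irregular census
polygons tiling its extent, a Niigata-like population of ~814,000 with
5-year age/sex composition, a centrally concentrated companies covariate,
case counts generated from the published demand model with noise
calibrated to its reported fit, and 35 candidate ambulance sites with 5
slots each.

Design notes on the defaults (see docs/methods.md for the full account):

* Census small areas in Japan are enumeration blocks drawn to hold
  broadly comparable numbers of households, so the population dispersion
  across areas is moderate (log-normal density noise, sd 0.15 on the log,
  plus a mild centre-weighted gradient), while the demographic
  *composition* varies strongly across blocks — young-family estates vs
  aged districts.  Composition heterogeneity is a per-area Dirichlet
  perturbation of the city-wide age/sex profile (concentration 30).
* The companies covariate is a proxy for diurnal commuter flux and is
  drawn with its own, steeper central gradient and over-dispersed
  (gamma-mixed Poisson) noise so that it is not collinear with resident
  population.
* Case-count noise is Gaussian on the model mean, then floored at zero
  and rounded — matching the OLS generating assumption so the R-squared
  calibration has a closed form.  A Poisson option is available.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from . import reference
from .errors import CalibrationError, ParameterError, StateError
from .network import envelope_centroid
from .regression import StepwiseOLS, niigata_demand_model

__all__ = [
    "CensusAreas",
    "SyntheticCity",
    "generate_road_graph",
    "generate_census_areas",
    "japan_age_profile",
    "populate_demographics",
    "assign_admin_areas",
    "simulate_case_counts",
    "calibrate_noise_to_r2",
    "scatter_case_points",
    "place_candidate_sites",
    "generate_city",
]

SEXES = ["male", "female"]


# ---------------------------------------------------------------------------
# containers

@dataclass
class CensusAreas:
    """Census small areas: attribute table plus polygon geometry.

    ``table`` is indexed by ``area_id`` and carries envelope centroids and,
    once populated, demographic counts and case counts.  ``age_sex`` is the
    long-format sex x 5-year-band count table.
    """

    table: pd.DataFrame
    polygons: dict[int, Polygon]
    age_sex: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["centroid_x", "centroid_y"]].to_numpy()


@dataclass
class SyntheticCity:
    """A complete synthetic planning instance."""

    graph: nx.Graph
    areas: CensusAreas
    sites: pd.DataFrame
    model: StepwiseOLS
    noise_sd: float
    case_points: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# road graph

def generate_road_graph(n_rows: int, n_cols: int, spacing_m: float,
                        jitter_frac: float = 0.0,
                        edge_removal_frac: float = 0.0,
                        seed: int = 0) -> nx.Graph:
    """Perturbed-lattice road network.

    Nodes sit on an ``n_rows x n_cols`` grid with ``spacing_m`` metres
    between neighbours, jittered by up to ``jitter_frac * spacing_m`` in
    each coordinate.  A fraction of edges is removed at random, but never
    in a way that disconnects the graph (such removals are re-inserted).
    """
    if n_rows < 2 or n_cols < 2:
        raise ParameterError("need n_rows >= 2 and n_cols >= 2")
    if not (0 <= edge_removal_frac < 0.3):
        raise ParameterError(
            f"edge_removal_frac must be in [0, 0.3), got {edge_removal_frac}")
    if not (0 <= jitter_frac < 0.5):
        raise ParameterError(
            f"jitter_frac must be in [0, 0.5), got {jitter_frac}")
    if spacing_m <= 0:
        raise ParameterError("spacing_m must be positive")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    for r in range(n_rows):
        for c in range(n_cols):
            nid = r * n_cols + c
            jx, jy = rng.uniform(-jitter_frac, jitter_frac, 2) * spacing_m
            g.add_node(nid, x=c * spacing_m + jx, y=r * spacing_m + jy)

    def _length(u, v):
        return float(np.hypot(g.nodes[u]["x"] - g.nodes[v]["x"],
                              g.nodes[u]["y"] - g.nodes[v]["y"]))

    for r in range(n_rows):
        for c in range(n_cols):
            nid = r * n_cols + c
            if c + 1 < n_cols:
                g.add_edge(nid, nid + 1, length_m=_length(nid, nid + 1))
            if r + 1 < n_rows:
                g.add_edge(nid, nid + n_cols,
                           length_m=_length(nid, nid + n_cols))

    if edge_removal_frac > 0:
        edges = sorted(g.edges)
        n_remove = int(round(edge_removal_frac * len(edges)))
        for ei in rng.choice(len(edges), size=n_remove, replace=False):
            u, v = edges[ei]
            data = g.edges[u, v]
            g.remove_edge(u, v)
            if not nx.is_connected(g):
                g.add_edge(u, v, **data)  # would disconnect: re-insert
    xs = [g.nodes[n]["x"] for n in g]
    ys = [g.nodes[n]["y"] for n in g]
    g.graph["bbox"] = (min(xs), min(ys), max(xs), max(ys))
    return g


# ---------------------------------------------------------------------------
# census polygons

def generate_census_areas(graph: nx.Graph, k: int, seed: int = 0) -> CensusAreas:
    """Tile the graph's bounding box with ``k`` Voronoi census polygons.

    Seed points are uniform in the box; cells are clipped to it, so the
    polygons partition the box exactly.  Centroids are envelope centres,
    the study's centroid convention.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if graph.number_of_nodes() == 0:
        raise ParameterError("graph is empty")
    xmin, ymin, xmax, ymax = graph.graph.get(
        "bbox",
        (min(nx.get_node_attributes(graph, "x").values()),
         min(nx.get_node_attributes(graph, "y").values()),
         max(nx.get_node_attributes(graph, "x").values()),
         max(nx.get_node_attributes(graph, "y").values())),
    )
    bbox = box(xmin, ymin, xmax, ymax)
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(xmin, xmax, k),
                           rng.uniform(ymin, ymax, k)])
    if len(np.unique(pts, axis=0)) < k:
        raise ParameterError(f"could not place {k} distinct seed points")
    if k == 1:
        polys = {0: bbox}
    else:
        cells = voronoi_diagram(MultiPoint(pts.tolist()), envelope=bbox)
        tree = STRtree(list(cells.geoms))
        polys = {}
        for i, (x, y) in enumerate(pts):
            hits = tree.query(Point(x, y), predicate="intersects")
            if len(hits) == 0:
                raise ParameterError("Voronoi cell lookup failed")
            cell = cells.geoms[int(hits[0])].intersection(bbox)
            polys[i] = cell
    rows = []
    for i in sorted(polys):
        cx, cy = envelope_centroid(polys[i])
        rows.append((i, cx, cy, polys[i].area))
    table = pd.DataFrame(rows, columns=["area_id", "centroid_x",
                                        "centroid_y", "polygon_area"])
    table = table.set_index("area_id")
    return CensusAreas(table=table, polygons=polys)


# ---------------------------------------------------------------------------
# demographics

def japan_age_profile() -> pd.DataFrame:
    """City-wide age/sex profile (proportions of total population).

    Shaped on the mid-2000s Japanese age pyramid: band shares peak in the
    30s and late 50s, ~5.9% of the population is 80 or over, and the male
    fraction declines from ~51% at birth to ~35% at 85+.
    """
    band_share = np.array([4.4, 4.7, 4.7, 5.2, 5.8, 6.3, 7.7, 6.6, 6.3,
                           6.2, 7.0, 8.0, 6.7, 6.3, 5.7, 4.5, 3.1, 2.9])
    band_share = band_share / band_share.sum()
    mids = np.arange(2.5, 92.5, 5.0)
    male_frac = np.clip(0.515 - 0.0025 * np.maximum(0.0, mids - 30.0),
                        0.30, 0.52)
    prof = pd.DataFrame(
        {"male": band_share * male_frac,
         "female": band_share * (1 - male_frac)},
        index=pd.Index(reference.AGE_BANDS, name="band"),
    )
    return prof / prof.to_numpy().sum()


def _centre_distance_norm(areas: CensusAreas) -> np.ndarray:
    """Per-area distance from the city centre, normalised to [0, 1]."""
    c = areas.centroids
    centre = (c.min(axis=0) + c.max(axis=0)) / 2.0
    d = np.hypot(*(c - centre).T)
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def populate_demographics(areas: CensusAreas, total_pop: int,
                          age_profile: pd.DataFrame | None = None,
                          company_intensity: float = 5.0,
                          urban_gradient: float = 0.5,
                          seed: int = 0,
                          dirichlet_conc: float = 30.0,
                          company_gradient: float = 2.0,
                          density_log_sd: float = 0.15) -> CensusAreas:
    """Draw per-area populations, age/sex composition and company counts.

    The total population is allocated multinomially across areas with a
    centre-weighted density gradient; each area's sex x band composition
    is a Dirichlet perturbation of the city profile; companies get their
    own steeper central gradient with over-dispersed counts.
    """
    if total_pop < 0:
        raise ParameterError("total_pop must be non-negative")
    if age_profile is None:
        age_profile = japan_age_profile()
    p = age_profile.to_numpy(dtype=float)  # bands x sexes
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError("age_profile proportions must sum to 1")
    rng = np.random.default_rng(seed)
    k = len(areas)
    dnorm = _centre_distance_norm(areas)

    w = np.exp(-urban_gradient * dnorm)
    w = w * rng.lognormal(0.0, density_log_sd, k) if density_log_sd > 0 else w
    w = w / w.sum()
    pop = rng.multinomial(total_pop, w)

    flat = (age_profile["male"].tolist() + age_profile["female"].tolist())
    flat = np.asarray(flat, dtype=float)
    nb = len(age_profile)
    if dirichlet_conc > 0:
        # alpha_i = conc * p_i: mean is the city profile, dispersion ~ 1/conc
        probs = rng.dirichlet(np.maximum(dirichlet_conc * flat, 1e-6), size=k)
    else:
        probs = np.tile(flat, (k, 1))
    counts = rng.multinomial(pop, probs)  # k x (2*nb)
    male = counts[:, :nb]
    female = counts[:, nb:]

    wc = np.exp(-company_gradient * dnorm) * rng.gamma(1.0, 1.0, k)
    wc = wc / wc.sum()
    companies = rng.poisson(k * company_intensity * wc)

    bands = list(age_profile.index)
    b80 = bands.index("80-84")
    b65 = bands.index("65-69")
    b15 = bands.index("15-19")
    b64 = bands.index("60-64")
    tot_by_band = male + female
    tab = areas.table
    tab["pop_total"] = pop
    tab["pop_0_4"] = tot_by_band[:, 0]
    tab["pop_15_64"] = tot_by_band[:, b15:b64 + 1].sum(axis=1)
    tab["pop_65_over"] = tot_by_band[:, b65:].sum(axis=1)
    tab["pop_80_over"] = tot_by_band[:, b80:].sum(axis=1)
    tab["companies_5plus"] = companies

    long = []
    for j, band in enumerate(bands):
        long.append(pd.DataFrame({
            "area_id": tab.index, "sex": "male", "band": band,
            "count": male[:, j]}))
        long.append(pd.DataFrame({
            "area_id": tab.index, "sex": "female", "band": band,
            "count": female[:, j]}))
    areas.age_sex = pd.concat(long, ignore_index=True)
    return areas


def assign_admin_areas(areas: CensusAreas, n_admin: int = 38,
                       seed: int = 0) -> CensusAreas:
    """Group census areas into administrative areas (nearest of n seeds)."""
    if n_admin < 1:
        raise ParameterError("n_admin must be >= 1")
    rng = np.random.default_rng(seed)
    c = areas.centroids
    lo, hi = c.min(axis=0), c.max(axis=0)
    seeds = rng.uniform(lo, hi, size=(n_admin, 2))
    d = np.hypot(c[:, None, 0] - seeds[None, :, 0],
                 c[:, None, 1] - seeds[None, :, 1])
    areas.table["admin_id"] = d.argmin(axis=1)
    return areas


# ---------------------------------------------------------------------------
# case counts

def simulate_case_counts(areas: CensusAreas, model: StepwiseOLS,
                         noise_sd: float, seed: int = 0,
                         family: str = "gaussian") -> CensusAreas:
    """Draw per-area observed EMS case counts around the model mean.

    Gaussian family: ``observed = round(max(0, mu + eps))`` with
    ``eps ~ N(0, noise_sd)`` — negative means are floored at zero because
    counts cannot be negative.  Poisson family: ``observed ~ Pois(max(0, mu))``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    mu = model.predict(areas.table, clip_negative=False)
    rng = np.random.default_rng(seed)
    if family == "gaussian":
        y = np.rint(np.maximum(0.0, mu + rng.normal(0.0, noise_sd, len(mu))))
    elif family == "poisson":
        y = rng.poisson(np.maximum(0.0, mu)).astype(float)
    else:
        raise ParameterError(f"unknown noise family {family!r}")
    areas.table["mean_cases"] = mu
    areas.table["observed_cases"] = y.astype(int)
    return areas


def calibrate_noise_to_r2(areas: CensusAreas, model: StepwiseOLS,
                          target_r2: float) -> float:
    """Noise sd such that var(mu) / (var(mu) + sd^2) equals the target.

    Closed form: ``sd = sd(mu) * sqrt(1/R2 - 1)``.
    """
    if not (0 < target_r2 < 1):
        raise ParameterError("target_r2 must be in (0, 1)")
    mu = model.predict(areas.table, clip_negative=False)
    s = float(np.std(mu))
    if s == 0:
        raise CalibrationError("model mean is constant across areas")
    return s * float(np.sqrt(1.0 / target_r2 - 1.0))


# ---------------------------------------------------------------------------
# case points

def _uniform_points_in_polygon(poly: Polygon, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        cand = np.column_stack([rng.uniform(xmin, xmax, m),
                                rng.uniform(ymin, ymax, m)])
        inside = [poly.covers(Point(x, y)) for x, y in cand]
        take = cand[np.asarray(inside, dtype=bool)][: n - got]
        out[got:got + len(take)] = take
        got += len(take)
    return out


def scatter_case_points(areas: CensusAreas, seed: int = 0,
                        tag_demographics: bool = True) -> pd.DataFrame:
    """Scatter each area's observed cases uniformly inside its polygon.

    Points carry their generating ``area_id`` (the round-trip oracle for
    point-in-polygon counting).  When demographics are present, each case
    is tagged with an age band and sex sampled in proportion to the
    area's population weighted by the published age/sex monthly use rates
    (flat to age 54, rising steeply past 55).
    """
    if "observed_cases" not in areas.table.columns:
        raise StateError("observed_cases not set; run simulate_case_counts")
    rng = np.random.default_rng(seed)
    rates = reference.MONTHLY_USERS_PER_1000_BY_AGE.to_numpy()
    sex_rate = reference.MONTHLY_USERS_PER_1000_BY_SEX
    bands = reference.AGE_BANDS
    if tag_demographics and areas.age_sex is not None:
        wide = areas.age_sex.pivot_table(index="area_id", columns=["sex", "band"],
                                         values="count", fill_value=0)
    else:
        wide = None
    rows = []
    for aid, rec in areas.table.iterrows():
        n = int(rec["observed_cases"])
        if n == 0:
            continue
        pts = _uniform_points_in_polygon(areas.polygons[aid], n, rng)
        if wide is not None:
            wts = np.array([
                wide.loc[aid].get((sex, band), 0) * rates[j]
                * sex_rate[sex]
                for sex in SEXES for j, band in enumerate(bands)
            ], dtype=float)
            if wts.sum() <= 0:
                wts = np.array([rates[j] * sex_rate[sex]
                                for sex in SEXES for j, _ in enumerate(bands)])
            wts = wts / wts.sum()
            draws = rng.choice(len(wts), size=n, p=wts)
            sexes = [SEXES[d // len(bands)] for d in draws]
            bnds = [bands[d % len(bands)] for d in draws]
        else:
            sexes = [None] * n
            bnds = [None] * n
        for i in range(n):
            rows.append((pts[i, 0], pts[i, 1], aid, sexes[i], bnds[i]))
    out = pd.DataFrame(rows, columns=["x", "y", "area_id", "sex", "band"])
    out.index.name = "case_id"
    return out


# ---------------------------------------------------------------------------
# candidate sites

def place_candidate_sites(graph: nx.Graph, n_sites: int = 35,
                          slots_per_site: int = 5,
                          seed: int = 0) -> pd.DataFrame:
    """Candidate ambulance sites at distinct road-graph nodes."""
    nodes = sorted(graph.nodes)
    if n_sites > len(nodes):
        raise ParameterError(
            f"n_sites={n_sites} exceeds node count {len(nodes)}")
    if slots_per_site < 1:
        raise ParameterError("slots_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(nodes), size=n_sites, replace=False))
    rows = []
    for sid, ni in enumerate(chosen):
        node = nodes[ni]
        rows.append((sid, node, graph.nodes[node]["x"],
                     graph.nodes[node]["y"], slots_per_site))
    out = pd.DataFrame(rows, columns=["site_id", "node", "x", "y",
                                      "max_slots"]).set_index("site_id")
    return out


# ---------------------------------------------------------------------------
# cohort inputs

def admin_cohort_table(areas: CensusAreas, period: int = 2005):
    """Aggregate the per-area age/sex table to administrative areas."""
    from .cohort import CohortTable
    if areas.age_sex is None or "admin_id" not in areas.table.columns:
        raise StateError("demographics and admin assignment required first")
    df = areas.age_sex.copy()
    df["admin_id"] = df["area_id"].map(areas.table["admin_id"])
    agg = (df.groupby(["admin_id", "sex", "band"])["count"].sum()
           .reset_index())
    return CohortTable(period=period, data=agg)


def synthesize_prior_census(pop_t5, seed: int = 0,
                            ratio_noise_sd: float = 0.02):
    """A synthetic earlier census consistent with plausible cohort ratios.

    Back-casts each admin area's table five years by inverting an assumed
    cohort-change-ratio schedule (near 1 below age 50, falling to ~0.55
    for the open-ended band, log-normal migration noise per sex x band).
    Used where only one synthetic census exists but the projector needs
    two; the implied forward ratios reproduce an ageing, slowly shrinking
    city.
    """
    from .cohort import BANDS, CohortTable, SEXES
    rng = np.random.default_rng(seed)
    mids = np.arange(2.5, 92.5, 5.0)
    age_past_20 = np.maximum(mids - 20.0, 0.0)
    sched = np.where(mids <= 50, 0.995,
                     np.maximum(0.55, 1.03 - 0.0009 * age_past_20 ** 1.35))
    wide5 = pop_t5.pivot()
    wide0 = pd.DataFrame(0.0, index=wide5.index, columns=wide5.columns)
    for sex in SEXES:
        noise = rng.lognormal(0.0, ratio_noise_sd, len(BANDS))
        r = np.clip(sched * noise, 0.05, 1.05)
        for b in range(1, len(BANDS) - 1):
            # source band b-1 at t0 feeds band b at t5
            wide0[(sex, BANDS[b - 1])] = wide5[sex][BANDS[b]] / r[b]
        pooled = wide5[sex][BANDS[-1]] / (0.55 * noise[-1])
        wide0[(sex, BANDS[-2])] = pooled * 0.55
        wide0[(sex, BANDS[-1])] = pooled * 0.45
    out = CohortTable.from_pivot(pop_t5.period - 5, wide0.round(0))
    return out


# ---------------------------------------------------------------------------
# one-call generator

def generate_city(seed: int = 0, *,
                  n_rows: int = 40, n_cols: int = 40, spacing_m: float = 500.0,
                  jitter_frac: float = 0.2, edge_removal_frac: float = 0.1,
                  n_areas: int = reference.N_CENSUS_AREAS,
                  total_pop: int = reference.TOTAL_POPULATION,
                  company_intensity: float = 5.0,
                  urban_gradient: float = 0.5,
                  dirichlet_conc: float = 30.0,
                  company_gradient: float = 2.0,
                  density_log_sd: float = 0.15,
                  n_sites: int = reference.N_SITES,
                  slots_per_site: int = reference.SLOTS_PER_SITE,
                  n_admin: int = reference.N_ADMIN_AREAS,
                  model: StepwiseOLS | None = None,
                  target_r2: float = reference.NIIGATA_MODEL_R_SQUARED,
                  noise_family: str = "gaussian",
                  scatter_points: bool = False) -> SyntheticCity:
    """Generate a complete synthetic city at (by default) study scale.

    All sub-generators are driven by independent streams spawned from the
    one master seed, so the whole city is a pure function of ``seed`` and
    the parameters.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)]
    if model is None:
        model = niigata_demand_model()
    graph = generate_road_graph(n_rows, n_cols, spacing_m, jitter_frac,
                                edge_removal_frac, seeds[0])
    areas = generate_census_areas(graph, n_areas, seeds[1])
    areas = populate_demographics(
        areas, total_pop, None, company_intensity, urban_gradient, seeds[2],
        dirichlet_conc=dirichlet_conc, company_gradient=company_gradient,
        density_log_sd=density_log_sd)
    areas = assign_admin_areas(areas, n_admin, seeds[2])
    noise_sd = calibrate_noise_to_r2(areas, model, target_r2)
    areas = simulate_case_counts(areas, model, noise_sd, seeds[3],
                                 family=noise_family)
    sites = place_candidate_sites(graph, n_sites, slots_per_site, seeds[4])
    pts = scatter_case_points(areas, seeds[5]) if scatter_points else None
    return SyntheticCity(
        graph=graph, areas=areas, sites=sites, model=model,
        noise_sd=noise_sd, case_points=pts,
        params=dict(seed=seed, n_areas=n_areas, total_pop=total_pop,
                    n_sites=n_sites, slots_per_site=slots_per_site,
                    target_r2=target_r2, noise_family=noise_family),
    )
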