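"""Grouping genetic algorithm for the ambulance p-median problem.

The planning question is a weighted p-median: choose ``n`` ambulance
slots among the candidate slots (35 sites x 5 slots = 175 at study
scale) minimising the total case-weighted network distance from every
census area to its nearest *chosen site* — "person distance".  Duplicate
slots at one site never change this fitness (they matter for deployment
ranks downstream, not for nearest-site distance), so the exact oracle
enumerates distinct-site subsets.

The GA operators act on slot subsets (grouping-GA style, not positional
bit-strings): crossover keeps the parents' common slots and fills the
remainder greedily from the symmetric difference by marginal fitness
gain; mutation replaces slots with uniform unused ones; selection is
size-3 tournament with elitism, so the best-so-far trace is
non-increasing by construction.  All tie-breaks are by lowest site id,
making every run bit-reproducible per seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ParameterError

__all__ = [
    "LocationSet",
    "GAResult",
    "AmbulanceLocationGA",
    "fitness",
    "candidate_slots_from_sites",
    "init_population",
    "crossover",
    "mutate",
    "evolve",
    "brute_force_optimum",
]

Slot = tuple[int, int]  # (site_id, slot_index)


@dataclass(frozen=True)
class LocationSet:
    """A chromosome: a set of chosen (site_id, slot_index) slots."""

    slots: tuple[Slot, ...]

    def __post_init__(self):
        slots = tuple(sorted((int(s), int(k)) for s, k in self.slots))
        if len(set(slots)) != len(slots):
            raise ParameterError("duplicate (site, slot) pairs in chromosome")
        object.__setattr__(self, "slots", slots)

    @property
    def n(self) -> int:
        return len(self.slots)

    @property
    def sites(self) -> tuple[int, ...]:
        """Distinct chosen sites, sorted."""
        return tuple(sorted({s for s, _ in self.slots}))

    @classmethod
    def from_sites(cls, sites) -> "LocationSet":
        return cls(tuple((int(s), 0) for s in sites))


@dataclass
class GAResult:
    best: LocationSet
    best_fitness: float
    history: list[float]
    evaluations: int


def candidate_slots_from_sites(sites: pd.DataFrame) -> list[Slot]:
    """Expand a site table (index site_id, column max_slots) into slots."""
    out = []
    for sid, rec in sites.iterrows():
        for k in range(int(rec["max_slots"])):
            out.append((int(sid), k))
    return sorted(out)


# ---------------------------------------------------------------------------
# fitness

def _site_columns(od: pd.DataFrame) -> dict[int, int]:
    return {int(s): j for j, s in enumerate(od.columns)}


def _check_weights(od: pd.DataFrame, weights) -> np.ndarray:
    w = np.asarray(
        weights.reindex(od.index) if isinstance(weights, pd.Series)
        else weights, dtype=float)
    if len(w) != len(od):
        raise ParameterError("weights length does not match OD rows")
    if (w < 0).any() or np.isnan(w).any():
        raise ParameterError("weights must be >= 0")
    return w


def fitness(s: LocationSet, od: pd.DataFrame, weights) -> float:
    """Total person-distance of a location set.

    ``F(s) = sum_i w_i * min over distinct sites in s of d(i, site)``.
    Computed by grouping areas by their nearest chosen site and summing
    per-site person-distances, so it equals the catchment decomposition
    bit-for-bit.
    """
    if s.n == 0:
        raise ParameterError("empty location set has no fitness")
    cols = _site_columns(od)
    missing = [x for x in s.sites if x not in cols]
    if missing:
        raise ParameterError(f"sites not in OD matrix: {missing}")
    w = _check_weights(od, weights)
    D = od.to_numpy()[:, [cols[x] for x in s.sites]]
    nearest = D.argmin(axis=1)  # ties -> first = lowest site id (sorted cols)
    dmin = D[np.arange(len(D)), nearest]
    contrib = w * dmin
    per_site = [contrib[nearest == j].sum() for j in range(len(s.sites))]
    return float(np.sum(per_site))


def _fast_fitness(site_cols: np.ndarray, D: np.ndarray,
                  w: np.ndarray) -> float:
    return float(w @ D[:, site_cols].min(axis=1))


# ---------------------------------------------------------------------------
# operators

def init_population(n: int, population_size: int,
                    candidate_slots: list[Slot],
                    seed: int = 0) -> list[LocationSet]:
    """Uniform random n-slot subsets, distinct where possible."""
    if n > len(candidate_slots):
        raise ParameterError(
            f"n={n} exceeds {len(candidate_slots)} candidate slots")
    if n < 1 or population_size < 2:
        raise ParameterError("need n >= 1 and population_size >= 2")
    rng = np.random.default_rng(seed)
    slots = sorted(candidate_slots)
    pop, seen = [], set()
    tries = 0
    while len(pop) < population_size:
        pick = rng.choice(len(slots), size=n, replace=False)
        chrom = tuple(sorted(slots[i] for i in pick))
        tries += 1
        if chrom in seen and tries < 20 * population_size:
            continue
        seen.add(chrom)
        pop.append(LocationSet(chrom))
    return pop


def crossover(p1: LocationSet, p2: LocationSet, od: pd.DataFrame,
              weights, seed: int | None = None) -> LocationSet:
    """Intersection-preserving greedy-fill crossover.

    The child keeps the slots common to both parents and fills up to
    ``n`` from the symmetric difference, each time adding the slot with
    the best marginal fitness gain (ties: lowest site id, then slot
    index).  Deterministic given the parents; ``seed`` is accepted for
    operator-API uniformity and unused.
    """
    if p1.n != p2.n:
        raise ParameterError("parents must have equal size")
    cols = _site_columns(od)
    return _crossover_core(p1, p2, cols, od.to_numpy(),
                           _check_weights(od, weights))


def _crossover_core(p1: LocationSet, p2: LocationSet, cols: dict,
                    D: np.ndarray, w: np.ndarray) -> LocationSet:
    child = sorted(set(p1.slots) & set(p2.slots))
    cands = sorted(set(p1.slots) ^ set(p2.slots))
    m = (D[:, [cols[s] for s in sorted({x for x, _ in child})]].min(axis=1)
         if child else np.full(len(D), np.inf))
    while len(child) < p1.n:
        cand_cols = np.array([cols[s] for s, _ in cands])
        vals = w @ np.minimum(m[:, None], D[:, cand_cols])
        j = int(np.argmin(vals))  # first minimum = lowest (site, slot)
        chosen = cands.pop(j)
        child.append(chosen)
        m = np.minimum(m, D[:, cols[chosen[0]]])
    return LocationSet(tuple(child))


def mutate(s: LocationSet, rate: float, candidate_slots: list[Slot],
           seed: int = 0) -> LocationSet:
    """Replace each slot independently with probability ``rate``.

    Replacements are drawn uniformly from the slots not currently in the
    chromosome, sequentially, so the size is preserved.
    """
    if not (0 <= rate <= 1):
        raise ParameterError("mutation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    current = list(s.slots)
    pool = sorted(candidate_slots)
    flip = rng.random(len(current)) < rate
    for i in np.flatnonzero(flip):
        unused = [c for c in pool if c not in current]
        if not unused:
            break
        current[i] = unused[rng.integers(len(unused))]
    return LocationSet(tuple(current))


# ---------------------------------------------------------------------------
# the GA

class AmbulanceLocationGA(BaseEstimator):
    """Grouping GA selecting ``n`` ambulance slots (sklearn-style).

    ``fit(od, weights)`` runs the GA on an OD matrix (areas x sites,
    metres) with per-area case weights; fitted attributes expose the best
    location set, its person-distance and the per-generation best trace.
    ``predict(od)`` returns each area's nearest chosen site (the
    catchment labelling).

    Defaults follow standard grouping-GA practice: population 100,
    tournament size 3, elitism 2, crossover rate 0.9, per-slot mutation
    rate 0.05, 1500 generations (the study's iteration budget).
    """

    def __init__(self, n: int = 27, population_size: int = 100,
                 generations: int = 1500, crossover_rate: float = 0.9,
                 mutation_rate: float = 0.05, tournament_size: int = 3,
                 elitism_count: int = 2, early_stop: int | None = None,
                 random_state: int = 0):
        self.n = n
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.elitism_count = elitism_count
        self.early_stop = early_stop
        self.random_state = random_state

    def _validate(self, n_slots: int):
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if not (1 <= self.elitism_count < self.population_size):
            raise ParameterError("need 1 <= elitism_count < population_size")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.n < 1 or self.n > n_slots:
            raise ParameterError(
                f"n={self.n} outside [1, {n_slots}] candidate slots")

    def fit(self, od: pd.DataFrame, weights, candidate_slots=None):
        if candidate_slots is None:
            candidate_slots = [(int(s), 0) for s in od.columns]
        candidate_slots = sorted(candidate_slots)
        self._validate(len(candidate_slots))
        cols = _site_columns(od)
        D = od.to_numpy()
        w = _check_weights(od, weights)
        slot_arr = candidate_slots
        rng = np.random.default_rng(self.random_state)

        def seed32():
            return int(rng.integers(2**31 - 1))

        def evaluate(chrom: LocationSet) -> float:
            site_cols = np.array([cols[x] for x in chrom.sites])
            return _fast_fitness(site_cols, D, w)

        pop = init_population(self.n, self.population_size, slot_arr,
                              seed=seed32())
        fits = np.array([evaluate(c) for c in pop])
        evals = len(pop)
        history = [float(fits.min())]
        stall = 0
        for _ in range(self.generations):
            order = np.argsort(fits, kind="stable")
            new = [pop[i] for i in order[: self.elitism_count]]
            while len(new) < self.population_size:
                i1 = self._tournament(rng, fits)
                if rng.random() < self.crossover_rate:
                    i2 = self._tournament(rng, fits)
                    child = _crossover_core(pop[i1], pop[i2], cols, D, w)
                else:
                    child = pop[i1]
                if self.mutation_rate > 0:
                    child = mutate(child, self.mutation_rate, slot_arr,
                                   seed=seed32())
                new.append(child)
            pop = new
            fits = np.array([evaluate(c) for c in pop])
            evals += len(pop)
            best = float(fits.min())
            if best < history[-1]:
                stall = 0
            else:
                stall += 1
            history.append(min(best, history[-1]))
            if self.early_stop is not None and stall >= self.early_stop:
                break
        ibest = int(np.argmin(fits))
        # the elite guarantees pop contains the best-ever chromosome
        self.best_set_ = pop[ibest]
        self.best_fitness_ = history[-1]
        self.history_ = history
        self.n_evaluations_ = evals
        self.result_ = GAResult(self.best_set_, self.best_fitness_,
                                history, evals)
        return self

    def _tournament(self, rng, fits) -> int:
        idx = rng.integers(len(fits), size=self.tournament_size)
        return int(idx[np.argmin(fits[idx])])

    def predict(self, od: pd.DataFrame) -> np.ndarray:
        """Nearest chosen site for each OD row (catchment labels)."""
        check_is_fitted(self, "best_set_")
        cols = _site_columns(od)
        sites = self.best_set_.sites
        D = od.to_numpy()[:, [cols[s] for s in sites]]
        return np.asarray(sites)[D.argmin(axis=1)]


def evolve(od: pd.DataFrame, weights, candidate_slots, n: int,
           population_size: int = 100, generations: int = 1500,
           crossover_rate: float = 0.9, mutation_rate: float = 0.05,
           tournament_size: int = 3, elitism_count: int = 2,
           early_stop: int | None = None, seed: int = 0) -> GAResult:
    """Functional wrapper around :class:`AmbulanceLocationGA`."""
    ga = AmbulanceLocationGA(
        n=n, population_size=population_size, generations=generations,
        crossover_rate=crossover_rate, mutation_rate=mutation_rate,
        tournament_size=tournament_size, elitism_count=elitism_count,
        early_stop=early_stop, random_state=seed,
    ).fit(od, weights, candidate_slots)
    return ga.result_


# ---------------------------------------------------------------------------
# exact oracle

def brute_force_optimum(od: pd.DataFrame, weights, n: int,
                        max_subsets: int = 10**6
                        ) -> tuple[LocationSet, float]:
    """Exact p-median optimum by exhaustive distinct-site enumeration.

    Ties resolve to the lexicographically smallest site-id subset
    (combinations are enumerated in that order and only strict
    improvements replace the incumbent).
    """
    sites = sorted(int(s) for s in od.columns)
    if n < 1 or n > len(sites):
        raise ParameterError(f"n={n} outside [1, {len(sites)}]")
    count = math.comb(len(sites), n)
    if count > max_subsets:
        raise ParameterError(
            f"{count} subsets exceed the enumeration cap {max_subsets}")
    cols = _site_columns(od)
    D = od.to_numpy()
    w = _check_weights(od, weights)
    best, best_f = None, np.inf
    for combo in itertools.combinations(sites, n):
        f = _fast_fitness(np.array([cols[s] for s in combo]), D, w)
        if f < best_f:
            best, best_f = combo, f
    return LocationSet.from_sites(best), float(best_f)
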