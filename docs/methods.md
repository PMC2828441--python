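# Methods

This note documents the models, the synthetic-data design, the numerical
conventions, and the limits of what the test suite demonstrates.

## Demand regression

Per-area EMS case counts are modelled by ordinary least squares on
census predictors with forward-entry / backward-removal stepwise
selection on partial-F p-values (`p_enter = 0.05`, `p_remove = 0.10`,
the classical defaults of the stepwise procedure; `p_enter ≤ p_remove`
is enforced to preclude cycling, and a revisited predictor set raises an
error).  Selection by partial-F rather than AIC matches the semantics of
the stepwise tool used in the original analysis.  Conventions:

* R² of a zero-variance response is defined as 0 (the intercept-only
  model explains nothing rather than being undefined).
* Rank-deficient designs raise an error naming the collinear columns
  (identified by pivoted QR).
* Predictions for planning are clipped at zero by default — negative
  expected case counts are not meaningful — but the raw affine value is
  always available (`clip_negative=False`) for diagnostics, and the
  published intercept (−0.268) is only observable unclipped.
* The default candidate set offered to selection is
  `pop_0_4, pop_15_64, pop_65_over, pop_80_over, companies_5plus`.  The
  original candidate list included every 5-year band above 65; whether
  those were offered individually is ambiguous, so the list is a
  parameter.  Offering the aggregate 65+ alongside 80+ lets selection
  demonstrate that the generating band wins.

OLS estimation (coefficients, standard errors, p-values, R²) is
delegated to statsmodels; the selection loop is this package's.

## Synthetic cities

The generator replaces confidential inputs with seeded synthetic data of
the same structure and scale.  Every generator is a pure function of its
parameters and seed; a master seed spawns independent sub-streams.

* **Road network** — a jittered lattice (default 40×40 nodes, 500 m
  spacing, 20% jitter) with 10% of edges removed at random; removals
  that would disconnect the graph are re-inserted, so a single connected
  component is guaranteed.
* **Census polygons** — Voronoi cells of uniform seed points clipped to
  the network's bounding box: irregular, space-filling, cheap, and with
  envelope centroids that genuinely differ from area centroids (the
  envelope-centre convention is the study's).  Cells partition the box
  exactly (tested to 1e-6 relative).
* **Population** — 814,000 people multinomially allocated over 2076
  areas (mean 392/area).  Area weights combine a mild central gradient
  (`exp(-0.5·d̂)`) with log-normal density noise (sd 0.15 on the log):
  Japanese census small areas are enumeration blocks drawn to hold
  broadly comparable household counts, so area-population dispersion is
  moderate.  Age/sex composition (18 five-year bands × 2 sexes, open at
  85+) is a per-area Dirichlet perturbation (concentration 30) of a
  mid-2000s Japanese age pyramid: composition varies strongly across
  blocks — young-family estates versus aged districts — which is what
  makes the band-specific regression coefficients identifiable.
* **Companies** — gamma-mixed Poisson counts (mean 5/area) with a
  steeper central gradient (`exp(-2·d̂)`) than population, so the
  daytime-flux covariate is informative and not collinear with
  residents.
* **Case counts** — `y = round(max(0, μ + ε))` with `μ` from the
  published model and `ε ~ N(0, σ)`.  Gaussian-then-round (not Poisson)
  matches the OLS generating assumption and gives the calibration a
  closed form: `σ = sd(μ)·sqrt(1/R² − 1)` targets the published
  R² = 0.71 exactly in the variance decomposition.  A Poisson option
  exists behind `family="poisson"`.  The zero-floor is required (counts
  cannot be negative) and is rare under the defaults because per-area
  means sit well above σ.
* **Case points** — each area's count scattered uniformly in its
  polygon and tagged with its generating area (the exact round-trip
  oracle for point-in-polygon counting), plus an age band and sex drawn
  proportionally to area population weighted by the published monthly
  use rates per 1,000 (flat from 15–54, rising steeply past 55).
* **Prior census** — the projector needs two censuses; a synthetic
  2000 table is back-cast from the 2005 aggregate by inverting an
  assumed cohort-ratio schedule (≈1 below age 50 falling to ~0.55 for
  the open band, log-normal migration noise).  It is labelled synthetic
  and exists so the implied forward ratios give an ageing, slowly
  shrinking city.

What the generator does **not** emulate: real street topology and
one-way restrictions, true Japanese geography, spatial autocorrelation
of demand beyond the density gradients, diurnal variation, and case
severity.  Tests passing on synthetic cities therefore demonstrate the
correctness and internal consistency of the pipeline under its stated
assumptions, not predictive validity on any real city.

## Cohort projection

Hamilton–Perry cohort-change ratios: `r[sex, b] = P_t5[b] / P_t0[b−1]`
estimated on the city aggregate from two censuses five years apart;
mortality and net migration are absorbed into one factor.  The open
85+ band pools the two oldest source bands.  Zero base cohorts fall back
to a floor ratio (0.01) with a warning.  Births over a 5-year step are
`Σ(women 15–49) · (TFR/35) · 5` — a flat annual rate over the
reproductive span, since only a single total fertility rate (1.22) is
available — split 105:100 male:female and scaled by a childhood-survival
factor (default 1).  Projections run from 2005 in 5-year steps to a
configurable horizon (default 2040; the original work states both 2040
and 2050, so the horizon is a free parameter).

Disaggregation multiplies each census area's (sex, band) count by its
administrative area's projected/base growth factor, which conserves
admin totals exactly wherever the base count is nonzero.  Company counts
are frozen at baseline (a sensitivity multiplier is exposed), matching
the constant-socio-economic-covariates assumption.

## Network analysis

Coordinates are planar metres; no geodesy.  Demand and supply points are
snapped to their nearest road node (Euclidean; ties to the lowest node
id) and OD entries are node-to-node shortest-path lengths — one Dijkstra
per site, since sites are few and areas many.  Snap displacement is
logged for audit; partial-edge offsets are deliberately not modelled so
that distances are deterministic and oracle-testable against an
independent all-pairs Floyd–Warshall.  A disconnected origin–destination
pair is an error rather than an infinite distance: the GA fitness would
silently absorb ∞.  Time conversion is `s = m · 3.6 / v` with a single
network-wide speed (default 30 km/h).

## Grouping GA

Fitness is the weighted p-median objective over *distinct* sites;
duplicate slots at a site never change it (they matter for deployment
ranks, not nearest-site distance), so the exact oracle enumerates
distinct-site subsets (refusing above 10⁶).  The operators, standard
grouping-GA practice since the original operator design is unpublished:

* crossover keeps the parents' intersection and fills greedily from the
  symmetric difference by marginal fitness gain (deterministic; ties to
  the lowest site id) — the child never exceeds the worse parent;
* mutation replaces each slot independently (rate 0.05 by default) with
  a uniform unused slot, size-preserving;
* size-3 tournament selection with 2 elites; elitism makes the
  best-so-far trace non-increasing by construction;
* termination after a fixed generation count (default 1500, the study's
  budget); an optional no-improvement early stop is off by default.

All tie-breaks are by lowest id and every random draw is seeded, so runs
are bit-reproducible.  Population defaults to 100.  Problem sizes in the
test suite are scaled to what an exhaustive oracle can verify (≤ 500
subsets per instance, tens of generations); study-scale instances
(175 slots, 2076 areas) run through the same code path via the
`study` pipeline profile.

## Deployment model

Each case inherits its census area's OD row (the census-area demand
abstraction).  Units are ranked per area by distance, duplicate slots at
a site occupying consecutive ranks.  Availability is the simplest
mechanism consistent with nearest-available-ambulance dispatch: each
unit independently busy with probability `p`, first free unit responds,
the last unit unconditionally.  The rank-1 share is then exactly
`1 − p` (the nearest unit responds iff it is free), so the observed
67.8% rank-1 share calibrates `p = 0.322` directly; truncation only
affects the degenerate single-unit case.  Scenario comparisons are
paired on the same cases with the same uniform-draw stream (common
random numbers), and both a busy-model summary and a full-availability
summary are reported, since it is not stated which regime produced the
published optimal-scenario share.

Accounting identity: catchment person-distances are computed with the
same grouped summation as the fitness function, so their total equals
the fitness bit-for-bit, not merely to tolerance.

## Pipeline and problem sizes

The pipeline fits the demand model once on the current synthetic census
and applies it to each projected period's predictors; optimisations per
period are independent GA runs seeded from the master seed.  The demo
profile (200 areas, 12 sites × 2 slots, 300 generations) exercises every
stage in seconds and is the default; the study-scale profile (2076 areas,
35 × 5 slots, 1500 generations) is selected explicitly.  The
parameter-recovery study uses 20 seeded study-scale cities — enough for
simulation standard errors of ~0.5–1% of each coefficient — and the
GA-versus-oracle study uses 100 instances of 30 areas × 10 sites with
n = 3 (120 enumerable subsets each).

## Known limitations

* The availability model ignores queueing and spatial correlation of
  busy periods (no hypercube model); busyness is a demand index, not a
  utilisation forecast.
* Stepwise selection inherits the usual post-selection caveats: weak
  predictors (the 0–4 coefficient, 0.006) are selected only
  intermittently at the synthetic signal-to-noise level, which is why
  recovery checks target the three strong coefficients.
* Cohort ratios are held constant over the projection horizon; no
  probabilistic intervals.
* The flat 30 km/h speed ignores road class and time of day.
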