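"""Cohort-component population projection for administrative areas.

Future populations by sex and 5-year age band are projected in 5-year
steps with the Hamilton-Perry cohort-change-ratio method: the ratio of a
cohort's size at one census to the same cohort's size five years earlier
absorbs mortality and net migration in a single factor, so the method
needs exactly two census tables and a fertility rate.  Births over a
5-year step are ``sum(women 15-49) * (TFR / 35) * 5`` — a flat annual
rate over the reproductive ages, since only a single total fertility
rate (1.22 for the study city) is available — split by a sex ratio at
birth of 105 males per 100 females and survived into the 0-4 band.

Census-area predictor counts for future periods are obtained by scaling
each area's band counts by its administrative area's band-specific
growth factor (socio-economic covariates are held at baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import reference
from .errors import ParameterError

BANDS = reference.AGE_BANDS
SEXES = ["male", "female"]
FERTILE_BANDS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44",
                 "45-49"]

__all__ = [
    "CohortTable",
    "ProjectionParams",
    "CohortProjector",
    "cohort_change_ratios",
    "project_step",
    "project_series",
    "disaggregate_growth",
]


@dataclass
class CohortTable:
    """Population by administrative area x sex x 5-year band at one period.

    ``data`` is long format with columns ``admin_id, sex, band, count``.
    """

    period: int
    data: pd.DataFrame

    def __post_init__(self):
        need = {"admin_id", "sex", "band", "count"}
        missing = need - set(self.data.columns)
        if missing:
            raise ParameterError(f"cohort table missing columns {missing}")
        if (self.data["count"] < 0).any():
            raise ParameterError("cohort counts must be >= 0")
        bad = set(self.data["band"]) - set(BANDS)
        if bad:
            raise ParameterError(f"unknown age bands {sorted(bad)}")

    def pivot(self) -> pd.DataFrame:
        """admin_id x (sex, band) wide table, bands in age order."""
        wide = self.data.pivot_table(index="admin_id",
                                     columns=["sex", "band"],
                                     values="count", aggfunc="sum",
                                     fill_value=0.0)
        cols = pd.MultiIndex.from_product([SEXES, BANDS])
        return wide.reindex(columns=cols, fill_value=0.0)

    def total(self) -> float:
        return float(self.data["count"].sum())

    def band_totals(self) -> pd.Series:
        return self.data.groupby(["sex", "band"])["count"].sum()

    @classmethod
    def from_pivot(cls, period: int, wide: pd.DataFrame) -> "CohortTable":
        long = wide.stack([0, 1], future_stack=True).rename("count").reset_index()
        long.columns = ["admin_id", "sex", "band", "count"]
        return cls(period=period, data=long)


@dataclass
class ProjectionParams:
    """Knobs of the cohort projection."""

    cohort_change_ratios: pd.Series  # index (sex, band), band >= "5-9"
    total_fertility_rate: float = reference.TOTAL_FERTILITY_RATE
    sex_ratio_at_birth: float = 105.0  # males per 100 females
    childhood_survival: float = 1.0

    def __post_init__(self):
        if self.total_fertility_rate < 0:
            raise ParameterError("TFR must be >= 0")
        if not (0 < self.childhood_survival <= 1):
            raise ParameterError("childhood_survival must be in (0, 1]")
        if (self.cohort_change_ratios <= 0).any():
            raise ParameterError("cohort change ratios must be > 0")


def cohort_change_ratios(pop_t0: CohortTable, pop_t5: CohortTable,
                         ratio_floor: float = 0.01) -> pd.Series:
    """Ratios r[sex, b] = pop_t5[b] / pop_t0[b-1], cohorts followed forward.

    Computed on the city aggregate (summed over administrative areas).
    The open-ended 85+ band pools the last two source bands.  A zero
    denominator yields ``ratio_floor`` with a warning.
    """
    if pop_t5.period != pop_t0.period + 5:
        raise ParameterError("tables must be 5 years apart")
    t0 = pop_t0.band_totals()
    t5 = pop_t5.band_totals()
    out = {}
    for sex in SEXES:
        for j in range(1, len(BANDS)):
            band = BANDS[j]
            if band == BANDS[-1]:  # open-ended: pool 80-84 and 85+ sources
                denom = t0.get((sex, BANDS[-2]), 0) + t0.get((sex, BANDS[-1]), 0)
            else:
                denom = t0.get((sex, BANDS[j - 1]), 0)
            num = t5.get((sex, band), 0)
            if denom <= 0:
                warnings.warn(
                    f"zero base cohort for {sex} {band}; "
                    f"using floor ratio {ratio_floor}")
                out[(sex, band)] = ratio_floor
            else:
                out[(sex, band)] = max(float(num) / float(denom), ratio_floor)
    s = pd.Series(out, name="ratio")
    s.index.names = ["sex", "band"]
    return s


def _births(wide: pd.DataFrame, params: ProjectionParams) -> pd.Series:
    """5-year births per admin area, before the sex split."""
    women = wide["female"][FERTILE_BANDS].sum(axis=1)
    return women * (params.total_fertility_rate / 35.0) * 5.0


def project_step(pop_t: CohortTable, params: ProjectionParams) -> CohortTable:
    """Advance a cohort table one 5-year step."""
    wide = pop_t.pivot()
    out = pd.DataFrame(0.0, index=wide.index, columns=wide.columns)
    r = params.cohort_change_ratios
    for sex in SEXES:
        for j in range(1, len(BANDS)):
            band = BANDS[j]
            if band == BANDS[-1]:
                src = wide[sex][BANDS[-2]] + wide[sex][BANDS[-1]]
            else:
                src = wide[sex][BANDS[j - 1]]
            out[(sex, band)] = src * r[(sex, band)]
    births = _births(wide, params) * params.childhood_survival
    male_share = params.sex_ratio_at_birth / (100.0 + params.sex_ratio_at_birth)
    out[("male", BANDS[0])] = births * male_share
    out[("female", BANDS[0])] = births * (1.0 - male_share)
    return CohortTable.from_pivot(pop_t.period + 5, out)


def project_series(pop_2000: CohortTable, pop_2005: CohortTable,
                   params: ProjectionParams | None = None,
                   horizon_year: int = 2040) -> list[CohortTable]:
    """Project forward in 5-year periods from the later census.

    Ratios are estimated once from the two input censuses and applied
    repeatedly up to the horizon (default 2040).
    """
    base = pop_2005.period
    if horizon_year < base + 5 or horizon_year % 5 != 0:
        raise ParameterError(
            f"horizon must be a multiple of 5 and >= {base + 5}")
    if params is None:
        params = ProjectionParams(
            cohort_change_ratios=cohort_change_ratios(pop_2000, pop_2005))
    out = []
    cur = pop_2005
    for _ in range(base + 5, horizon_year + 1, 5):
        cur = project_step(cur, params)
        out.append(cur)
    return out


class CohortProjector(BaseEstimator):
    """Hamilton-Perry projector with an estimator interface.

    ``fit`` takes the two base censuses and stores the cohort-change
    ratios; ``project`` rolls them forward to the horizon.
    """

    def __init__(self, total_fertility_rate: float = reference.TOTAL_FERTILITY_RATE,
                 sex_ratio_at_birth: float = 105.0,
                 childhood_survival: float = 1.0,
                 ratio_floor: float = 0.01,
                 horizon: int = 2040):
        self.total_fertility_rate = total_fertility_rate
        self.sex_ratio_at_birth = sex_ratio_at_birth
        self.childhood_survival = childhood_survival
        self.ratio_floor = ratio_floor
        self.horizon = horizon

    def fit(self, pop_t0: CohortTable, pop_t5: CohortTable):
        self.ratios_ = cohort_change_ratios(pop_t0, pop_t5,
                                            self.ratio_floor)
        self.base_ = pop_t5
        self.params_ = ProjectionParams(
            cohort_change_ratios=self.ratios_,
            total_fertility_rate=self.total_fertility_rate,
            sex_ratio_at_birth=self.sex_ratio_at_birth,
            childhood_survival=self.childhood_survival)
        return self

    def project(self, horizon_year: int | None = None) -> list[CohortTable]:
        check_is_fitted(self, "params_")
        horizon = self.horizon if horizon_year is None else horizon_year
        out = []
        cur = self.base_
        if horizon < cur.period + 5 or horizon % 5 != 0:
            raise ParameterError(
                f"horizon must be a multiple of 5 and >= {cur.period + 5}")
        for _ in range(cur.period + 5, horizon + 1, 5):
            cur = project_step(cur, self.params_)
            out.append(cur)
        return out


def disaggregate_growth(admin_projection: list[CohortTable],
                        admin_base: CohortTable,
                        area_age_sex: pd.DataFrame,
                        membership: pd.Series) -> dict[int, pd.DataFrame]:
    """Scale census-area band counts by admin-area band growth factors.

    ``membership`` maps area_id -> admin_id (every census area to exactly
    one administrative area).  For each projected period, each area's
    (sex, band) count is multiplied by its admin area's factor
    ``projected / base`` for that (sex, band); the per-period result is a
    long table like ``area_age_sex``.  Conservation holds by construction:
    summing scaled member areas reproduces the admin projection wherever
    the base count is nonzero.
    """
    areas = area_age_sex["area_id"].unique()
    unmapped = set(areas) - set(membership.index)
    if unmapped:
        raise ParameterError(
            f"census areas without an admin mapping: {sorted(unmapped)[:5]}")
    base = admin_base.pivot()
    df = area_age_sex.copy()
    df["admin_id"] = df["area_id"].map(membership)
    # base admin totals must equal the aggregate of the member areas for
    # exact conservation; verify and fall back to the aggregate otherwise
    agg = df.pivot_table(index="admin_id", columns=["sex", "band"],
                         values="count", aggfunc="sum", fill_value=0.0)
    agg = agg.reindex(columns=base.columns, fill_value=0.0)
    out = {}
    for proj in admin_projection:
        target = proj.pivot().reindex(index=agg.index, fill_value=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = target.to_numpy() / agg.to_numpy()
        factor = np.where(agg.to_numpy() > 0, factor, 0.0)
        fdf = pd.DataFrame(factor, index=agg.index, columns=agg.columns)
        f = fdf.stack([0, 1], future_stack=True).rename("factor").reset_index()
        f.columns = ["admin_id", "sex", "band", "factor"]
        merged = df.merge(f, on=["admin_id", "sex", "band"], how="left")
        merged["count"] = merged["count"] * merged["factor"].fillna(0.0)
        out[proj.period] = merged[["area_id", "sex", "band", "count"]]
    return out


def predictor_table_from_age_sex(age_sex: pd.DataFrame,
                                 companies: pd.Series,
                                 company_growth: float = 1.0) -> pd.DataFrame:
    """Build the demand-model predictor table from a long age/sex table.

    Companies are frozen at baseline (optionally scaled by a sensitivity
    multiplier).
    """
    wide = age_sex.pivot_table(index="area_id", columns="band",
                               values="count", aggfunc="sum", fill_value=0.0)
    wide = wide.reindex(columns=BANDS, fill_value=0.0)
    i15, i64 = BANDS.index("15-19"), BANDS.index("60-64")
    i65, i80 = BANDS.index("65-69"), BANDS.index("80-84")
    out = pd.DataFrame(index=wide.index)
    out["pop_0_4"] = wide[BANDS[0]]
    out["pop_15_64"] = wide[BANDS[i15:i64 + 1]].sum(axis=1)
    out["pop_65_over"] = wide[BANDS[i65:]].sum(axis=1)
    out["pop_80_over"] = wide[BANDS[i80:]].sum(axis=1)
    out["companies_5plus"] = companies.reindex(wide.index) * company_growth
    return out
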