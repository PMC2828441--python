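"""Published Niigata City reference figures used as model inputs.

Niigata City (north-western Japan, ~804,000 inhabitants) runs a one-tiered
fire-department EMS system with 35 fire stations that can each host up to
five ambulances.  The figures below are the published summaries of the
21,211 geocoded ambulance call-outs of April-December 2007 and of the
stepwise demand regression fitted to the 2005 census small-area tables.
They serve two purposes here: they parameterise the synthetic-city
generator (age/sex case-rate shape, demand-model coefficients), and they
let the demographic summary operations be checked against printed values.
"""

from __future__ import annotations

import pandas as pd

#: 5-year age bands, open-ended at 85.
AGE_BANDS = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85+",
]

#: Geocoded EMS case counts by age band, Niigata April-December 2007.
#: Cases with unknown age are tallied separately; total cases 21,211.
EMS_CASES_BY_AGE = pd.Series(
    [841, 346, 322, 733, 954, 872, 876, 874, 704, 760, 892, 1399, 1254,
     1428, 1676, 2083, 2055, 2585],
    index=AGE_BANDS,
    name="cases",
)
EMS_CASES_AGE_UNKNOWN = 557

#: Geocoded EMS case counts by sex over the same period.
EMS_CASES_BY_SEX = pd.Series(
    {"male": 10791, "female": 9847}, name="cases"
)
EMS_CASES_SEX_UNKNOWN = 573

EMS_TOTAL_CASES = 21211

#: Monthly ambulance users per 1,000 population by age band.  Rates are
#: roughly flat from 15 to 54 and rise steeply past 55 — the shape the
#: synthetic case-tagging reproduces.
MONTHLY_USERS_PER_1000_BY_AGE = pd.Series(
    [2.77, 1.04, 0.92, 1.79, 2.20, 1.86, 1.63, 1.83, 1.55, 1.67, 1.67,
     2.35, 2.71, 3.42, 4.38, 6.54, 9.89, 13.96],
    index=AGE_BANDS,
    name="monthly_users_per_1000",
)

MONTHLY_USERS_PER_1000_BY_SEX = pd.Series(
    {"male": 3.05, "female": 2.60}, name="monthly_users_per_1000"
)

#: Stepwise-OLS demand model fitted to the 2076 Niigata census small areas:
#: cases = b0 + b1*pop_0_4 + b2*pop_15_64 + b3*pop_80_over
#:            + b4*companies_5plus
NIIGATA_MODEL_INTERCEPT = -0.268
NIIGATA_MODEL_COEFFICIENTS = pd.Series(
    {
        "pop_0_4": 0.006,
        "pop_15_64": 0.021,
        "pop_80_over": 0.102,
        "companies_5plus": 0.433,
    },
    name="coef",
)
NIIGATA_MODEL_STANDARD_ERRORS = pd.Series(
    {
        "pop_0_4": 0.001,
        "pop_15_64": 0.006,
        "pop_80_over": 0.006,
        "companies_5plus": 0.013,
    },
    name="se",
)
NIIGATA_MODEL_R_SQUARED = 0.71

#: Study-scale constants.
N_CENSUS_AREAS = 2076
N_SITES = 35
SLOTS_PER_SITE = 5
TOTAL_POPULATION = 814_000
TOTAL_FERTILITY_RATE = 1.22
N_ADMIN_AREAS = 38
OBSERVED_RANK1_SHARE = 0.678


def case_share_table(
    cases_by_age: pd.Series = EMS_CASES_BY_AGE,
    cases_by_sex: pd.Series = EMS_CASES_BY_SEX,
    age_unknown: int = EMS_CASES_AGE_UNKNOWN,
    sex_unknown: int = EMS_CASES_SEX_UNKNOWN,
) -> pd.DataFrame:
    """Recompute percentage shares of EMS cases by age band and sex.

    Shares are percentages of the grand total (including unknowns), as in
    published demographic breakdowns, rounded to one decimal place in the
    ``pct`` column; ``share`` keeps full precision.
    """
    total = int(cases_by_age.sum()) + int(age_unknown)
    total_sex = int(cases_by_sex.sum()) + int(sex_unknown)
    if total != total_sex:
        raise ValueError(
            f"age and sex tallies disagree: {total} vs {total_sex}"
        )
    rows = []
    for band, count in cases_by_age.items():
        rows.append(("age", band, int(count)))
    rows.append(("age", "unknown", int(age_unknown)))
    for sex, count in cases_by_sex.items():
        rows.append(("sex", sex, int(count)))
    rows.append(("sex", "unknown", int(sex_unknown)))
    out = pd.DataFrame(rows, columns=["dimension", "category", "cases"])
    out["share"] = out["cases"] / total
    out["pct"] = (100 * out["share"]).round(1)
    return out


def elderly_share(min_band: str = "75-79") -> float:
    """Share of EMS cases at or above the given age band (fraction)."""
    i = AGE_BANDS.index(min_band)
    return float(EMS_CASES_BY_AGE.iloc[i:].sum()) / EMS_TOTAL_CASES
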