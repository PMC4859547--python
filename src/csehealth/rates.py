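"""Age-standardised hospitalisation rates and quintile-level death rates.

PPH rates are directly age-standardised: the per-area rate is a weighted sum
of the age-group-specific rates (0-4, 5-9, 10-14) with weights equal to the
standard population's age shares, so areas with different age structures are
comparable.  Person-years for a financial year use the December population,
estimated as the mean of the adjacent June estimated resident populations.
Rates for multiple financial years are averaged (mean of yearly standardised
rates) to damp small-area stochastic variation.

Avoidable deaths are too rare for per-area rates; deaths and populations are
pooled within quintiles instead, and the pooled 0-14 rate is applied to the
quintile's 0-15 population to estimate deaths on the population scale used
for quintile construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .indicators import AGE_GROUPS
from .index import QuintileAssignment


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group shares of a standard population (must sum to 1)."""

    shares: Mapping[str, float]
    label: str

    def __post_init__(self) -> None:
        missing = [g for g in AGE_GROUPS if g not in self.shares]
        if missing:
            raise ValueError(f"standard population missing age group(s): {missing}")
        vals = [self.shares[g] for g in AGE_GROUPS]
        if any(v <= 0 for v in vals):
            raise ValueError("standard-population shares must be positive")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("standard-population shares must sum to 1")


# Synthetic placeholder standard (NOT official census figures): near-uniform
# child age structure, used by the simulations and tests.  Analyses of real
# data must supply the official standard-population shares via configuration.
SYNTHETIC_STANDARD_POPULATION = StandardPopulation(
    shares={"0-4": 0.34, "5-9": 0.33, "10-14": 0.33},
    label="synthetic placeholder standard population",
)


def december_population(june_before: float, june_after: float) -> float:
    """December ERP estimated as the mean of the adjacent June ERPs."""
    if june_before < 0 or june_after < 0:
        raise ValueError("population counts must be non-negative")
    return (june_before + june_after) / 2.0


def age_standardised_rate(
    counts: Mapping[str, float],
    pops: Mapping[str, float],
    std: StandardPopulation,
) -> float:
    """Directly age-standardised event rate per 1,000 person-years."""
    total = 0.0
    for g in AGE_GROUPS:
        c = float(counts.get(g, 0.0))
        p = float(pops.get(g, 0.0))
        if c > 0 and p <= 0:
            raise ValueError(f"age group {g!r} has events but zero population")
        if p > 0:
            total += std.shares[g] * (c / p)
    return 1000.0 * total


def mean_annual_pph_rate(
    events: pd.DataFrame,
    june_pops: pd.DataFrame,
    year_bounds: Mapping[str, tuple[int, int]],
    std: StandardPopulation,
) -> pd.DataFrame:
    """Per-area mean annual age-standardised PPH rate over the given years.

    ``events`` has columns (area_id, year, age_group, count); ``june_pops``
    has (area_id, june_year, age_group, pop).  ``year_bounds`` maps each
    financial-year label to its (preceding, subsequent) June years.  Areas
    present in ``june_pops`` but with no events get rate 0.  Returns a
    DataFrame with columns (area_id, rate) and an attribute-style record of
    the years used.
    """
    if not year_bounds:
        raise ValueError("at least one year is required")
    years = sorted(year_bounds)

    pop_lut = june_pops.set_index(["area_id", "june_year", "age_group"])["pop"]
    area_ids = sorted(june_pops["area_id"].unique())

    ev = events.set_index(["area_id", "year", "age_group"])["count"]

    rates = np.zeros(len(area_ids))
    for i, aid in enumerate(area_ids):
        yearly = []
        for year in years:
            jb, ja = year_bounds[year]
            counts, pops = {}, {}
            for g in AGE_GROUPS:
                try:
                    before = float(pop_lut[(aid, jb, g)])
                    after = float(pop_lut[(aid, ja, g)])
                except KeyError:
                    raise ValueError(
                        f"area {aid!r} is missing a June population for year {year!r}"
                    ) from None
                pops[g] = december_population(before, after)
                counts[g] = float(ev.get((aid, year, g), 0.0))
            yearly.append(age_standardised_rate(counts, pops, std))
        rates[i] = float(np.mean(yearly))

    out = pd.DataFrame({"area_id": area_ids, "rate": rates})
    out.attrs["years_used"] = years
    out.attrs["standard"] = std.label
    return out


def quintile_death_rates(
    deaths: pd.Series,
    pops_0_14: pd.Series,
    quintiles: QuintileAssignment,
    pops_0_15: pd.Series,
) -> pd.DataFrame:
    """Pooled avoidable-death rates and estimated 0-15 deaths per quintile.

    Rate = sum(deaths) / sum(0-14 population) within each quintile; estimated
    deaths among 0-15 year olds = rate x quintile 0-15 population (kept
    unrounded in ``est_deaths``; ``est_deaths_rounded`` is for display).
    """
    q = quintiles.quintile
    missing = q.index.difference(deaths.index).union(
        q.index.difference(pops_0_14.index)
    ).union(q.index.difference(pops_0_15.index))
    if len(missing):
        raise ValueError(f"quintiled areas missing death/population data: {list(missing)[:5]}")

    df = pd.DataFrame(
        {
            "quintile": q,
            "deaths": deaths.reindex(q.index),
            "pop_0_14": pops_0_14.reindex(q.index),
            "pop_0_15": pops_0_15.reindex(q.index),
        }
    )
    grouped = df.groupby("quintile").sum()
    if (grouped["pop_0_14"] <= 0).any():
        bad = grouped.index[grouped["pop_0_14"] <= 0].tolist()
        raise ValueError(f"quintile(s) with zero population: {bad}")
    grouped["rate"] = grouped["deaths"] / grouped["pop_0_14"]
    grouped["est_deaths"] = grouped["rate"] * grouped["pop_0_15"]
    grouped["est_deaths_rounded"] = grouped["est_deaths"].round().astype(int)
    return grouped.reset_index()
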