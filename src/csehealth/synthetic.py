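"""Synthetic small-area data with the structure the analysis assumes.

A single latent disadvantage factor ``z`` per area loads positively on all 13
social-exclusion indicators.  Proportion indicators are logistic functions of
``z`` plus noise; the three service/outcome ratios decrease in ``z`` (higher
latent disadvantage, poorer access), so they invert under orientation just as
the real indicators do.  Child populations are right-skewed (log-normal),
areas fall into the five ABS remoteness categories, hospitalisation counts are
Poisson with a log-rate increasing in ``z`` and an additive log-excess in
remote categories, and avoidable deaths are rare Poisson events whose rate
also increases in ``z``.

The retained latent vector makes parameter-recovery tests possible: a correct
index construction must track ``z``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .indicators import AGE_GROUPS, INDICATOR_NAMES, ORIENTATION_OF, RATIO_INVERTED, REMOTENESS_CATEGORIES

# Baseline location and latent-scale constants per indicator.  Proportion
# indicators use a logit intercept; ratio indicators use a log-scale mean and a
# multiplier applied to (loading * z + noise) before the sign flip.
_PROP_LOGIT_BASE = {
    "sole_parent_family": -1.6,
    "bottom_income_quintile": -1.4,
    "no_parent_in_paid_work": -1.9,
    "no_year12_in_family": -0.8,
    "aedi_below_10th_percentile": -2.2,
    "no_internet_at_home": -1.1,
    "no_parent_volunteering": 0.3,
    "no_motor_vehicle": -2.5,
    "rent_stress_30_40": -2.0,
    "overcrowding": -2.3,
}
_RATIO_LOG_BASE = {"naplan_score_ratio": 0.0, "gp_ratio": 0.0, "dentist_ratio": -0.9}
_RATIO_LOG_SCALE = {"naplan_score_ratio": 0.05, "gp_ratio": 0.4, "dentist_ratio": 0.4}

_FIRST_JUNE_YEAR = 2006


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in SimulationConfig field {name!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic small-area generator.

    Defaults emulate the national study conditions: 1154 analysed areas,
    remoteness mix matching the published area counts per category, a mean
    avoidable-death rate of ~23 per 100,000 child-years, and PPH rates in the
    low-20s per 1,000 child-years with a remote-area excess.
    """

    n_areas: int = 1154
    seed: int = 0
    latent_sd: float = 1.0
    indicator_loadings: tuple[float, ...] = tuple([1.0] * 13)
    indicator_noise_sd: float = 0.5
    child_pop_log_mean: float = 7.6
    child_pop_log_sd: float = 1.0
    remoteness_probs: tuple[float, ...] = (0.34, 0.24, 0.26, 0.075, 0.085)
    pph_baseline_log_rate: float = -3.8  # log(events per child-year)
    pph_disadvantage_slope: float = 0.4
    pph_remote_excess: tuple[float, ...] = (0.0, 0.0, 0.0, 0.35, 0.45)
    death_rate_per_100k: float = 23.0
    death_disadvantage_slope: float = 0.3
    n_years: int = 3
    age_group_shares: tuple[float, ...] = (0.34, 0.33, 0.33)
    # Fixture switches for exercising the exclusion rules: these many areas are
    # forced below the child-population threshold; ``n_force_both`` of them
    # additionally receive one indicator non-response fraction >= 0.8.
    n_force_low_pop: int = 0
    n_force_both: int = 0

    def __post_init__(self) -> None:
        if self.n_areas <= 0:
            raise ValueError("n_areas must be a positive integer")
        for name in (
            "latent_sd",
            "indicator_noise_sd",
            "child_pop_log_sd",
            "death_rate_per_100k",
        ):
            v = getattr(self, name)
            _check_finite(name, v)
            if v <= 0 and name != "indicator_noise_sd":
                raise ValueError(f"{name} must be strictly positive")
            if name == "indicator_noise_sd" and v < 0:
                raise ValueError("indicator_noise_sd must be non-negative")
        for name in (
            "child_pop_log_mean",
            "pph_baseline_log_rate",
            "pph_disadvantage_slope",
            "death_disadvantage_slope",
        ):
            _check_finite(name, getattr(self, name))
        if len(self.indicator_loadings) != 13:
            raise ValueError("indicator_loadings must have exactly 13 entries")
        _check_finite("indicator_loadings", self.indicator_loadings)
        if len(self.remoteness_probs) != 5:
            raise ValueError("remoteness_probs must have exactly 5 entries")
        _check_finite("remoteness_probs", self.remoteness_probs)
        if abs(sum(self.remoteness_probs) - 1.0) > 1e-9:
            raise ValueError("remoteness_probs must sum to 1")
        if len(self.pph_remote_excess) != 5:
            raise ValueError("pph_remote_excess must have exactly 5 entries")
        _check_finite("pph_remote_excess", self.pph_remote_excess)
        if len(self.age_group_shares) != 3:
            raise ValueError("age_group_shares must have exactly 3 entries")
        _check_finite("age_group_shares", self.age_group_shares)
        if abs(sum(self.age_group_shares) - 1.0) > 1e-9:
            raise ValueError("age_group_shares must sum to 1")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")
        if self.n_force_low_pop < 0 or self.n_force_both < 0:
            raise ValueError("forced-exclusion counts must be non-negative")
        if self.n_force_low_pop + self.n_force_both > self.n_areas:
            raise ValueError("forced-exclusion counts exceed n_areas")


@dataclass
class SyntheticDataset:
    """One generated small-area dataset plus its ground truth.

    ``areas`` carries per-area attributes (child population 0-15, remoteness,
    per-indicator non-response fractions ``nr_<indicator>``); ``age_pops``
    holds June estimated resident populations by age group; ``indicators`` the
    raw (un-oriented) indicator values; ``pph_counts`` hospitalisation events
    per area x financial year x age group; ``death_counts`` avoidable deaths
    per area x calendar year; ``latent`` the generating disadvantage factor.
    """

    areas: pd.DataFrame
    age_pops: pd.DataFrame
    indicators: pd.DataFrame
    pph_counts: pd.DataFrame
    death_counts: pd.DataFrame
    latent: pd.Series
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def june_years(self) -> list[int]:
        return sorted(self.age_pops["june_year"].unique())

    @property
    def financial_years(self) -> list[str]:
        return sorted(self.pph_counts["year"].unique())

    def year_bounds(self) -> dict[str, tuple[int, int]]:
        """Map financial-year label -> (preceding June year, subsequent June year)."""
        out = {}
        for label in self.financial_years:
            start = int(label.split("-")[0])
            out[label] = (start, start + 1)
        return out


def financial_year_label(start: int) -> str:
    return f"{start}-{str(start + 1)[-2:]}"


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; identical configs give identical tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_areas
    width = max(4, len(str(n)))
    area_ids = np.array([f"A{i:0{width}d}" for i in range(1, n + 1)])

    z = rng.normal(0.0, config.latent_sd, size=n)

    ind = {}
    loadings = dict(zip(INDICATOR_NAMES, config.indicator_loadings))
    for name in INDICATOR_NAMES:
        noise = rng.normal(0.0, config.indicator_noise_sd, size=n)
        signal = loadings[name] * z + noise
        if ORIENTATION_OF[name] == RATIO_INVERTED:
            # Higher disadvantage -> lower ratio (worse access / worse scores).
            ind[name] = np.exp(_RATIO_LOG_BASE[name] - _RATIO_LOG_SCALE[name] * signal)
        else:
            ind[name] = expit(_PROP_LOGIT_BASE[name] + signal)

    child_pop = np.round(
        rng.lognormal(config.child_pop_log_mean, config.child_pop_log_sd, size=n)
    ).astype(int)
    child_pop = np.maximum(child_pop, 1)

    remoteness_idx = rng.choice(5, size=n, p=np.asarray(config.remoteness_probs))
    remoteness = np.array(REMOTENESS_CATEGORIES, dtype=object)[remoteness_idx]

    # Non-response fractions: mostly tiny, occasionally larger.
    nr = rng.beta(1.2, 60.0, size=(n, 13))

    # Forced-exclusion fixtures (drawn last so upstream draws are unaffected).
    n_forced = config.n_force_low_pop + config.n_force_both
    if n_forced:
        forced = rng.choice(n, size=n_forced, replace=False)
        child_pop[forced] = rng.integers(1, 30, size=n_forced)
        both = forced[config.n_force_low_pop:]
        if len(both):
            cols = rng.integers(0, 13, size=len(both))
            nr[both, cols] = rng.uniform(0.80, 1.0, size=len(both))

    pop_0_14 = np.round(child_pop * 15.0 / 16.0).astype(int)
    shares = np.asarray(config.age_group_shares)
    age_pop = np.floor(pop_0_14[:, None] * shares[None, :]).astype(int)
    age_pop[:, 0] += pop_0_14 - age_pop.sum(axis=1)  # remainder to youngest

    june_years = [_FIRST_JUNE_YEAR + k for k in range(config.n_years + 1)]
    fy_labels = [financial_year_label(y) for y in june_years[:-1]]

    # June ERPs held constant across years: December populations then equal the
    # June age-group populations, keeping rate calibration transparent.
    age_rows = []
    for jy in june_years:
        for g, group in enumerate(AGE_GROUPS):
            age_rows.append(
                pd.DataFrame(
                    {"area_id": area_ids, "june_year": jy, "age_group": group, "pop": age_pop[:, g]}
                )
            )
    age_pops = pd.concat(age_rows, ignore_index=True)

    log_rate = (
        config.pph_baseline_log_rate
        + config.pph_disadvantage_slope * z
        + np.asarray(config.pph_remote_excess)[remoteness_idx]
    )
    rate = np.exp(log_rate)
    pph_rows = []
    for label in fy_labels:
        for g, group in enumerate(AGE_GROUPS):
            counts = rng.poisson(age_pop[:, g] * rate)
            pph_rows.append(
                pd.DataFrame(
                    {"area_id": area_ids, "year": label, "age_group": group, "count": counts}
                )
            )
    pph_counts = pd.concat(pph_rows, ignore_index=True)

    death_mu = pop_0_14 * (config.death_rate_per_100k / 1e5) * np.exp(
        config.death_disadvantage_slope * z
    )
    death_rows = []
    for k in range(config.n_years):
        year = _FIRST_JUNE_YEAR + 1 + k
        deaths = rng.poisson(death_mu)
        death_rows.append(pd.DataFrame({"area_id": area_ids, "year": year, "count": deaths}))
    death_counts = pd.concat(death_rows, ignore_index=True)

    areas = pd.DataFrame(
        {
            "area_id": area_ids,
            "child_pop_0_15": child_pop,
            "pop_0_14": pop_0_14,
            "remoteness": remoteness,
        }
    )
    for j, name in enumerate(INDICATOR_NAMES):
        areas[f"nr_{name}"] = nr[:, j]

    indicators = pd.DataFrame({"area_id": area_ids, **ind})
    latent = pd.Series(z, index=pd.Index(area_ids, name="area_id"), name="latent")

    return SyntheticDataset(
        areas=areas,
        age_pops=age_pops,
        indicators=indicators,
        pph_counts=pph_counts,
        death_counts=death_counts,
        latent=latent,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset tables as UTF-8 CSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("areas", ds.areas),
        ("age_populations", ds.age_pops),
        ("indicators", ds.indicators),
        ("pph_counts", ds.pph_counts),
        ("death_counts", ds.death_counts),
        ("latent", ds.latent.reset_index()),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "seed": ds.config.seed,
        "n_areas": int(ds.config.n_areas),
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=float))
    paths["manifest"] = mp
    return paths


def crude_pph_rate(ds: SyntheticDataset) -> pd.Series:
    """Per-area crude PPH rate (events per 1,000 child-years, all years pooled)."""
    ev = ds.pph_counts.groupby("area_id")["count"].sum()
    pop = (
        ds.age_pops[ds.age_pops["june_year"].isin([b[0] for b in ds.year_bounds().values()])]
        .groupby("area_id")["pop"]
        .sum()
    )
    rate = 1000.0 * ev / pop.replace(0, np.nan)
    return rate.fillna(0.0)
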