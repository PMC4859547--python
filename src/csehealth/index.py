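"""Construction of the composite Child Social Exclusion index.

Pipeline: exclude unreliable areas -> orient all 13 indicators so larger means
higher risk -> summarise each domain (first principal component for four
domains, arithmetic mean for housing, whose two indicators are weakly
correlated) -> map each domain score through the exponential rank
transformation used by deprivation indices of the IMD family -> average the
five transformed domain indices into the composite -> assign
child-population-weighted quintiles (quintile 1 = highest risk, each quintile
holding 20% of children rather than 20% of areas).

The exponential rank transformation is, for an area with ascending-risk rank
scaled to R = k/N (R = 1/N least deprived, R = 1 most deprived):

    X = -23 * ln(1 - R * (1 - exp(-100/23)))

which spreads the most deprived tail and fixes X = 100 exactly at R = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import (
    DOMAINS,
    HOUSING,
    INDICATOR_NAMES,
    ORIENTATION_OF,
    RATIO_INVERTED,
    domain_indicators,
)

DEFAULT_MIN_CHILDREN = 30
DEFAULT_MAX_NONRESPONSE = 0.80

_EXP_CONST = 1.0 - np.exp(-100.0 / 23.0)


@dataclass
class QuintileAssignment:
    """Population-weighted quintile membership (1 = highest risk / worst outcome)."""

    quintile: pd.Series  # area_id -> 1..5
    basis: str
    weights: pd.Series  # area_id -> child population used


@dataclass
class CompositeIndexResult:
    """Full per-area output of the index construction."""

    table: pd.DataFrame  # area_id index; raw_<domain>, X_<domain>, composite, quintile
    quintiles: QuintileAssignment
    excluded: pd.DataFrame  # area_id, low_population, low_response


def filter_areas(
    areas: pd.DataFrame,
    min_children: int = DEFAULT_MIN_CHILDREN,
    max_nonresponse: float = DEFAULT_MAX_NONRESPONSE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split areas into (included, excluded-with-reasons).

    An area is excluded iff its child population 0-15 is below ``min_children``
    or any indicator's non-response fraction is at or above
    ``max_nonresponse`` (the threshold is inclusive).
    """
    if len(areas) == 0:
        raise ValueError("no areas supplied")
    if not 0 < max_nonresponse <= 1:
        raise ValueError("max_nonresponse must lie in (0, 1]")
    if min_children < 0:
        raise ValueError("min_children must be non-negative")

    low_pop = areas["child_pop_0_15"] < min_children
    nr_cols = [c for c in areas.columns if c.startswith("nr_")]
    if nr_cols:
        low_resp = (areas[nr_cols] >= max_nonresponse).any(axis=1)
    else:
        low_resp = pd.Series(False, index=areas.index)

    bad = low_pop | low_resp
    excluded = pd.DataFrame(
        {
            "area_id": areas.loc[bad, "area_id"].to_numpy(),
            "low_population": low_pop[bad].to_numpy(),
            "low_response": low_resp[bad].to_numpy(),
        }
    )
    included = areas.loc[~bad].reset_index(drop=True)
    if len(included) == 0:
        raise ValueError(
            f"all areas excluded (min_children={min_children}, "
            f"max_nonresponse={max_nonresponse})"
        )
    return included, excluded


def orient_indicators(indicators: pd.DataFrame) -> pd.DataFrame:
    """Return indicators oriented so larger always means higher risk.

    Proportion indicators pass through unchanged; the inverted ratios (GP,
    dentist, test-score ratio) are negated, which exactly reverses their order.
    """
    missing = [n for n in INDICATOR_NAMES if n not in indicators.columns]
    if missing:
        raise ValueError(f"missing indicator columns: {missing}")
    bad_cols = {}
    for name in INDICATOR_NAMES:
        vals = indicators[name].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if not finite.all():
            bad_cols[name] = list(indicators.loc[~finite, "area_id"])
    if bad_cols:
        raise ValueError(f"non-finite indicator values: {bad_cols}")

    out = indicators.copy()
    for name in INDICATOR_NAMES:
        if ORIENTATION_OF[name] == RATIO_INVERTED:
            out[name] = -out[name]
    return out


def _standardise(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance indicator encountered during standardisation")
    return (values - mean) / sd


def score_domain_pca(oriented: pd.DataFrame, domain: str) -> pd.Series:
    """First-principal-component score of a domain's oriented indicators.

    Indicators are standardised to mean 0, unit variance over the included
    areas (correlation-matrix PCA, as the indicators are on incomparable
    scales).  The component sign is fixed so the score correlates positively
    with the unweighted mean of the domain's standardised oriented indicators:
    higher score = higher risk, deterministically and independently of any
    positive rescaling of an individual indicator.
    """
    if domain == HOUSING:
        raise ValueError("the housing domain is scored by score_domain_mean, not PCA")
    names = domain_indicators(domain)
    if len(oriented) < 3:
        raise ValueError("PCA domain scoring needs at least 3 areas")
    vals = oriented[names].to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    zero = [n for n, s in zip(names, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance indicator(s) in domain {domain!r}: {zero}")
    std = _standardise(vals)
    corr = np.corrcoef(std, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    leading = eigvecs[:, np.argmax(eigvals)]
    score = std @ leading
    # Orientation rule pins the sign (standardised mean, so the rule is
    # invariant to rescaling any single indicator).
    anchor = std.mean(axis=1)
    if np.corrcoef(score, anchor)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=oriented["area_id"].to_numpy(), name=f"raw_{domain}")


def score_domain_mean(oriented: pd.DataFrame, domain: str = HOUSING) -> pd.Series:
    """Arithmetic mean of the two housing proportions."""
    if domain != HOUSING:
        raise ValueError("score_domain_mean applies to the housing domain only")
    names = domain_indicators(domain)
    vals = oriented[names].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing housing indicator value")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("housing indicators must be proportions in [0, 1]")
    return pd.Series(
        vals.mean(axis=1), index=oriented["area_id"].to_numpy(), name=f"raw_{domain}"
    )


def exponential_rank_transform(scores) -> tuple[np.ndarray, np.ndarray]:
    """Map raw domain scores to scaled ranks R and transformed indices X.

    Ranks ascend in risk (rank 1 = least deprived); ties take consecutive
    ranks in stable input order so R is always exactly k/N and X(R=1) = 100.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no scores supplied")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite score supplied to the rank transform")
    n = s.size
    order = np.argsort(s, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    r = ranks / n
    x = -23.0 * np.log(1.0 - r * _EXP_CONST)
    return r, x


def composite_index(x: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the five transformed domain indices."""
    missing = [d for d in DOMAINS if f"X_{d}" not in x.columns]
    if missing:
        raise ValueError(f"missing transformed domain column(s): {missing}")
    cols = [f"X_{d}" for d in DOMAINS]
    vals = x[cols].to_numpy(dtype=float)
    if (vals <= 0).any() or (vals > 100).any():
        raise ValueError("transformed domain indices must lie in (0, 100]")
    return pd.Series(vals.mean(axis=1), index=x.index, name="composite")


def weighted_quintiles(
    basis: pd.Series,
    weights: pd.Series,
    basis_label: str = "composite",
) -> QuintileAssignment:
    """Assign population-weighted quintiles, highest basis value -> quintile 1.

    Areas are sorted by basis descending (ties broken by area id), the
    cumulative child population is accumulated, and an area joins quintile k
    when the midpoint of its cumulative-weight interval falls in
    ((k-1)/5, k/5] of the total.  Each quintile's population then deviates
    from 20% by at most the largest single-area weight.
    """
    basis = pd.Series(basis)
    weights = pd.Series(weights).reindex(basis.index)
    if weights.isna().any():
        raise ValueError("every area in basis needs a weight")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("total weight must be positive")
    if not np.all(np.isfinite(basis.to_numpy(dtype=float))):
        raise ValueError("basis values must be finite")

    # Tie-break by area_id for determinism.
    df = (
        pd.DataFrame({"basis": basis, "w": weights})
        .rename_axis("area_id")
        .reset_index()
        .sort_values(["basis", "area_id"], ascending=[False, True], kind="stable")
    )
    cum = df["w"].cumsum()
    mid = (cum - df["w"] / 2.0) / total
    q = np.ceil(mid.to_numpy() * 5.0).astype(int)
    q = np.clip(q, 1, 5)
    quintile = pd.Series(q, index=df["area_id"].to_numpy(), name="quintile")
    quintile = quintile.reindex(basis.index)
    return QuintileAssignment(
        quintile=quintile,
        basis=basis_label,
        weights=weights,
    )


def build_index(
    areas: pd.DataFrame,
    indicators: pd.DataFrame,
    min_children: int = DEFAULT_MIN_CHILDREN,
    max_nonresponse: float = DEFAULT_MAX_NONRESPONSE,
) -> CompositeIndexResult:
    """Run the full index construction and quintile assignment."""
    included, excluded = filter_areas(areas, min_children, max_nonresponse)
    ind = indicators[indicators["area_id"].isin(included["area_id"])].reset_index(drop=True)
    ind = ind.sort_values("area_id", kind="stable").reset_index(drop=True)
    included = included.sort_values("area_id", kind="stable").reset_index(drop=True)
    oriented = orient_indicators(ind)

    table = pd.DataFrame(index=pd.Index(oriented["area_id"].to_numpy(), name="area_id"))
    for domain in DOMAINS:
        if domain == HOUSING:
            raw = score_domain_mean(oriented, domain)
        else:
            raw = score_domain_pca(oriented, domain)
        _, x = exponential_rank_transform(raw.to_numpy())
        table[f"raw_{domain}"] = raw.to_numpy()
        table[f"X_{domain}"] = x
    table["composite"] = composite_index(table)

    weights = pd.Series(
        included["child_pop_0_15"].to_numpy(),
        index=included["area_id"].to_numpy(),
        name="child_pop_0_15",
    )
    qa = weighted_quintiles(table["composite"], weights, basis_label="composite")
    table["quintile"] = qa.quintile
    return CompositeIndexResult(table=table, quintiles=qa, excluded=excluded)


def domain_quintiles(result: CompositeIndexResult) -> dict[str, QuintileAssignment]:
    """Population-weighted quintiles for each of the five domain indices."""
    out = {}
    for domain in DOMAINS:
        out[domain] = weighted_quintiles(
            result.table[f"X_{domain}"], result.quintiles.weights, basis_label=domain
        )
    return out
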