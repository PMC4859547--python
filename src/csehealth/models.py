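"""Outcome models: polynomial index-rate regression, residuals by remoteness,
and avoidable-mortality contingency chi-squares.

The relationship between the composite index and the area PPH rate is fitted
by ordinary least squares on raw polynomial terms (index, index^2, index^3)
with backward stepwise elimination at alpha = 0.05 (intercept always kept).
Residuals from the final model flag areas with unexpectedly high or low rates
given their social-exclusion risk; grouping residuals by the five ABS
remoteness categories and testing with one-way ANOVA plus Tukey-Kramer
all-pairs comparisons isolates a remoteness effect beyond the index.

Quintile-level avoidable mortality is tested with a Pearson chi-square (no
continuity correction, df = 4) on the 5x2 table of deaths vs survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .association import _oneway_anova
from .indicators import REMOTENESS_CATEGORIES

logger = logging.getLogger(__name__)

_TERM_ORDER = ("index", "index^2", "index^3")


@dataclass
class RegressionFit:
    terms: tuple[str, ...]  # retained non-intercept terms
    coefficients: dict[str, float]  # includes "intercept"
    p_values: dict[str, float]
    r_squared: float
    residuals: pd.Series  # area_id -> observed - fitted


@dataclass
class RemotenessResidualTable:
    summary: pd.DataFrame  # remoteness, mean, sd, min, max, n
    anova: tuple[float, int, int, float]
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


@dataclass
class ContingencyResult:
    table: np.ndarray  # 5x2 (deaths, survivors)
    chi2: float
    df: int
    p: float


def _design(index: np.ndarray, terms: tuple[str, ...]) -> np.ndarray:
    cols = {"index": index, "index^2": index**2, "index^3": index**3}
    X = np.column_stack([cols[t] for t in terms]) if terms else np.empty((len(index), 0))
    return sm.add_constant(X, has_constant="add")


def _effective_pvalues(result, terms: tuple[str, ...], y: np.ndarray) -> np.ndarray:
    """p-values for the non-intercept terms, robust to perfect fits.

    With zero residual variance the usual t statistics are 0/0; a term whose
    contribution to the fitted values is numerically negligible is then
    treated as droppable (p = 1) and a term with real contribution as
    certain (p = 0).
    """
    pvals = np.asarray(result.pvalues[1:], dtype=float)
    if not np.isnan(pvals).any():
        return pvals
    scale_y = max(float(np.std(y)), 1.0)
    X = result.model.exog[:, 1:]
    for j in range(len(pvals)):
        if np.isnan(pvals[j]):
            contribution = abs(result.params[j + 1]) * float(np.std(X[:, j]))
            pvals[j] = 1.0 if contribution <= 1e-9 * scale_y else 0.0
    return pvals


def fit_polynomial(
    index: pd.Series,
    rates: pd.Series,
    max_degree: int = 3,
    alpha: float = 0.05,
) -> RegressionFit:
    """Backward-stepwise OLS of area rate on polynomial terms of the index.

    Starting from the full polynomial, the non-intercept term with the largest
    p-value >= alpha is dropped and the model refitted, until every remaining
    term is significant.  The final model never contains a term with
    p >= alpha.
    """
    index = pd.Series(index)
    rates = pd.Series(rates).reindex(index.index)
    if rates.isna().any():
        raise ValueError("every indexed area needs a rate")
    if len(index) < max_degree + 2:
        raise ValueError("too few areas for the requested polynomial degree")
    x = index.to_numpy(dtype=float)
    y = rates.to_numpy(dtype=float)

    terms = tuple(_TERM_ORDER[:max_degree])
    while True:
        X = _design(x, terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear polynomial design matrix")
        result = sm.OLS(y, X).fit()
        if not terms:
            break
        pvals = _effective_pvalues(result, terms, y)
        worst = int(np.argmax(pvals))
        if pvals[worst] >= alpha:
            terms = tuple(t for k, t in enumerate(terms) if k != worst)
            continue
        break

    coef = {"intercept": float(result.params[0])}
    pv = {"intercept": float(result.pvalues[0]) if np.isfinite(result.pvalues[0]) else 0.0}
    final_p = _effective_pvalues(result, terms, y) if terms else np.array([])
    for k, t in enumerate(terms):
        coef[t] = float(result.params[k + 1])
        pv[t] = float(final_p[k])
    fitted = result.fittedvalues
    residuals = pd.Series(y - fitted, index=index.index, name="residual")
    r2 = float(result.rsquared) if np.isfinite(result.rsquared) else 1.0
    return RegressionFit(
        terms=terms,
        coefficients=coef,
        p_values=pv,
        r_squared=max(0.0, min(1.0, r2)),
        residuals=residuals,
    )


def assign_remoteness(
    remoteness: str | None = None,
    sub_populations: Mapping[str, float] | None = None,
) -> str:
    """Remoteness category of an area, by majority population if split.

    Areas straddling several categories take the category holding the largest
    population; ties go to the more remote category (logged).
    """
    if sub_populations is not None:
        if not sub_populations:
            raise ValueError("empty sub-population map")
        total = sum(sub_populations.values())
        if total <= 0:
            raise ValueError("sub-populations must have positive total")
        best = max(
            sub_populations,
            key=lambda c: (sub_populations[c], REMOTENESS_CATEGORIES.index(c)),
        )
        top = [c for c, p in sub_populations.items() if p == sub_populations[best]]
        if len(top) > 1:
            logger.warning(
                "remoteness tie between %s; assigning the more remote category %r",
                sorted(top),
                best,
            )
        return best
    if remoteness is None:
        raise ValueError("provide a category or a sub-population map")
    if remoteness not in REMOTENESS_CATEGORIES:
        raise ValueError(f"unknown remoteness category {remoteness!r}")
    return remoteness


def residuals_by_remoteness(
    residuals: pd.Series,
    categories: pd.Series,
) -> RemotenessResidualTable:
    """Residual-rate summaries by remoteness with ANOVA and Tukey-Kramer."""
    cats = pd.Series(categories).reindex(residuals.index)
    if cats.isna().any():
        missing = list(residuals.index[cats.isna()])[:5]
        raise ValueError(f"areas without a remoteness category: {missing}")

    df = pd.DataFrame({"residual": residuals, "remoteness": cats})
    present = [c for c in REMOTENESS_CATEGORIES if (cats == c).any()]
    g = df.groupby("remoteness")["residual"]
    summary = pd.DataFrame(
        {
            "mean": g.mean(),
            "sd": g.std(ddof=1),
            "min": g.min(),
            "max": g.max(),
            "n": g.size(),
        }
    ).reindex(present).reset_index(names="remoteness")

    groups = [df.loc[df["remoteness"] == c, "residual"].to_numpy(dtype=float) for c in present]
    anova = _oneway_anova(groups)

    usable = [c for c, grp in zip(present, groups) if len(grp) >= 2]
    dropped = sorted(set(present) - set(usable))
    if dropped:
        logger.warning("remoteness categories with <2 areas excluded from Tukey: %s", dropped)
    sub = df[df["remoteness"].isin(usable)]
    tk = pairwise_tukeyhsd(sub["residual"].to_numpy(), sub["remoteness"].to_numpy())
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    return RemotenessResidualTable(summary=summary, anova=anova, tukey=tukey)


def mortality_chi_square(deaths, populations) -> ContingencyResult:
    """Pearson chi-square on the quintile deaths-vs-survivors table.

    No continuity correction; df = (number of quintiles - 1).  Swapping the
    deaths and survivors columns leaves the statistic unchanged.
    """
    d = np.asarray(deaths, dtype=float)
    p = np.asarray(populations, dtype=float)
    if (d < 0).any() or (p < 0).any():
        raise ValueError("counts must be non-negative")
    if (d > p).any():
        raise ValueError("deaths exceed population in at least one quintile")
    keep = p > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 quintiles with positive population")
    table = np.column_stack([d, p - d])
    res = stats.chi2_contingency(table[keep], correction=False)
    return ContingencyResult(
        table=table,
        chi2=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
    )
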