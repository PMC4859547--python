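"""Index-outcome association: weighted correlations, quintile concordance
cross-tabulations, quintile summaries, and gradient tests.

Correlations are Pearson coefficients weighted by each area's population of
0-15 year olds, so populous areas count proportionally.  Concordance between
an outcome quintile (e.g. PPH rate) and an index or domain quintile is
summarised by a 5x5 table of the percentage of children in each cell; the
diagonal is the share of children whose two quintile ranks agree, the
diagonal-plus-adjacent share allows a one-step discrepancy.  Differences in
mean area rates across quintiles are tested by one-way ANOVA, complemented by
Kruskal-Wallis and all-pairs Welch t-tests because rate variances differ
substantially between quintiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .index import QuintileAssignment


@dataclass
class CrossTab:
    """5x5 percentage-of-children concordance table (rows = outcome quintile)."""

    shares: pd.DataFrame  # 5x5, rows outcome quintile 1..5, cols index quintile 1..5
    row_totals: pd.Series
    col_totals: pd.Series
    diagonal_pct: float
    diagonal_adjacent_pct: float


@dataclass
class GradientTests:
    anova: tuple[float, int, int, float]  # F, df_between, df_within, p
    kruskal_wallis: tuple[float, int, float]  # chi2, df, p
    welch_pairs: dict[tuple[int, int], tuple[float, float, float]]  # (t, df, p)


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation with observation weights.

    r = sum w (x - xbar_w)(y - ybar_w) / sqrt(sum w (x - xbar_w)^2 * sum w (y - ybar_w)^2)
    with weighted means; reduces to the ordinary coefficient for equal weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if (w > 0).sum() < 3:
        raise ValueError("need at least 3 observations with positive weight")
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = np.sum(w * (x - xm) ** 2)
    syy = np.sum(w * (y - ym) ** 2)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero weighted variance")
    sxy = np.sum(w * (x - xm) * (y - ym))
    return float(sxy / np.sqrt(sxx * syy))


def diagonal_statistics(shares: np.ndarray) -> tuple[float, float]:
    """(diagonal %, diagonal-plus-adjacent %) of a 5x5 percentage table."""
    a = np.asarray(shares, dtype=float)
    diag = float(np.trace(a))
    adj = float(sum(a[i, j] for i in range(5) for j in range(5) if abs(i - j) <= 1))
    return diag, adj


def crosstab_from_shares(shares: np.ndarray) -> CrossTab:
    """Wrap an existing 5x5 percentage table (e.g. a published tabulation)."""
    a = np.asarray(shares, dtype=float)
    if a.shape != (5, 5):
        raise ValueError("expected a 5x5 table")
    df = pd.DataFrame(a, index=range(1, 6), columns=range(1, 6))
    diag, adj = diagonal_statistics(a)
    return CrossTab(
        shares=df,
        row_totals=df.sum(axis=1),
        col_totals=df.sum(axis=0),
        diagonal_pct=diag,
        diagonal_adjacent_pct=adj,
    )


def crosstab_shares(
    outcome_q: QuintileAssignment,
    index_q: QuintileAssignment,
    weights: pd.Series,
) -> CrossTab:
    """Percent of children in each (outcome quintile, index quintile) cell."""
    oq = outcome_q.quintile
    iq = index_q.quintile
    if not oq.index.sort_values().equals(iq.index.sort_values()):
        raise ValueError("the two quintile assignments cover different areas")
    w = pd.Series(weights).reindex(oq.index)
    if w.isna().any():
        raise ValueError("every area needs a weight")
    total = float(w.sum())
    if total <= 0:
        raise ValueError("total weight must be positive")

    cells = np.zeros((5, 5))
    iq = iq.reindex(oq.index)
    for aid in oq.index:
        cells[int(oq[aid]) - 1, int(iq[aid]) - 1] += float(w[aid])
    return crosstab_from_shares(100.0 * cells / total)


def quintile_summary(rates: pd.Series, quintiles: QuintileAssignment) -> pd.DataFrame:
    """Unweighted per-quintile mean, sample SD, min, max and n of area rates."""
    r = pd.Series(rates).reindex(quintiles.quintile.index)
    if r.isna().any():
        raise ValueError("every quintiled area needs a rate")
    df = pd.DataFrame({"quintile": quintiles.quintile, "rate": r})
    g = df.groupby("quintile")["rate"]
    out = pd.DataFrame(
        {
            "mean": g.mean(),
            "sd": g.std(ddof=1),
            "min": g.min(),
            "max": g.max(),
            "n": g.size(),
        }
    )
    if (out["n"] == 0).any():
        raise ValueError("empty quintile")
    return out.reset_index()


def _oneway_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA returning F = 0 (not NaN) when between-group SS is zero."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_between == 0:
        return 0.0, df_b, df_w, 1.0
    if ss_within == 0:
        return float("inf"), df_b, df_w, 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def gradient_tests(rates: pd.Series, quintiles: QuintileAssignment) -> GradientTests:
    """ANOVA, Kruskal-Wallis and all 10 pairwise Welch t-tests across quintiles."""
    r = pd.Series(rates).reindex(quintiles.quintile.index)
    df = pd.DataFrame({"quintile": quintiles.quintile, "rate": r})
    labels = sorted(df["quintile"].unique())
    groups = [df.loc[df["quintile"] == q, "rate"].to_numpy(dtype=float) for q in labels]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("each quintile needs at least 2 areas")

    anova = _oneway_anova(groups)
    try:
        kw_stat, kw_p = stats.kruskal(*groups)
    except ValueError:  # all values identical
        kw_stat, kw_p = 0.0, 1.0
    kw = (float(kw_stat), len(groups) - 1, float(kw_p))

    welch: dict[tuple[int, int], tuple[float, float, float]] = {}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            welch[(int(labels[a]), int(labels[b]))] = (
                float(res.statistic) if np.isfinite(res.statistic) else 0.0,
                float(res.df),
                float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
            )
    return GradientTests(anova=anova, kruskal_wallis=kw, welch_pairs=welch)
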