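"""Published national reference tabulations used for validation.

These are the printed quintile-level results of the national small-area study
of child social exclusion and child health outcomes (2006-boundary statistical
local areas, 1154 analysed areas): the 5x5 concordance tables of the share of
children by PPH-rate quintile and index/domain quintile, and the 2007
avoidable-death contingency counts per quintile.  The underlying unit records
are not redistributable, but these aggregate tables are sufficient inputs to
recompute the diagonal concordance statistics and the mortality chi-squares,
which regression tests compare against the published summary values.

Cell percentages were rounded to one decimal before publication, so sums
recomputed from the cells can differ from the published diagonal summaries by
about 0.1-0.2 percentage points for some tables.
"""

from __future__ import annotations

import numpy as np

# 5x5 share-of-children tables: rows = PPH quintile 1 (highest rate) .. 5,
# columns = index/domain quintile 1 (highest risk) .. 5.  Values in percent.
CROSSTAB_CELLS: dict[str, np.ndarray] = {
    "cse_index": np.array(
        [
            [7.3, 6.2, 3.5, 2.0, 1.1],
            [5.7, 4.6, 4.0, 3.9, 1.9],
            [2.3, 2.6, 5.1, 5.2, 5.1],
            [2.9, 4.5, 3.5, 4.2, 4.7],
            [1.6, 2.2, 3.9, 4.9, 7.3],
        ]
    ),
    "socioeconomic": np.array(
        [
            [8.3, 6.1, 3.4, 1.0, 1.2],
            [4.6, 5.8, 4.3, 3.4, 2.1],
            [1.9, 2.5, 6.1, 3.7, 6.0],
            [3.3, 3.5, 3.0, 5.5, 4.6],
            [1.8, 2.2, 3.3, 6.5, 6.2],
        ]
    ),
    "education": np.array(
        [
            [7.3, 6.0, 3.7, 2.7, 0.4],
            [4.2, 4.3, 4.7, 4.7, 2.2],
            [3.0, 3.5, 4.1, 4.5, 5.1],
            [2.8, 4.3, 3.9, 2.8, 6.0],
            [2.1, 2.3, 3.6, 5.5, 6.4],
        ]
    ),
    "connectedness": np.array(
        [
            [7.2, 5.5, 3.0, 2.5, 1.8],
            [5.9, 4.7, 4.3, 2.8, 2.4],
            [2.1, 4.4, 5.2, 3.9, 4.6],
            [3.1, 4.0, 3.5, 4.6, 4.7],
            [1.7, 1.3, 4.2, 6.2, 6.6],
        ]
    ),
    "housing": np.array(
        [
            [5.5, 6.0, 4.2, 2.1, 2.3],
            [6.8, 4.0, 3.9, 3.6, 1.8],
            [1.7, 3.7, 3.9, 5.9, 5.0],
            [3.5, 4.2, 4.4, 4.2, 3.5],
            [2.2, 2.0, 4.0, 4.3, 7.5],
        ]
    ),
    "health_services": np.array(
        [
            [3.9, 4.1, 4.6, 4.7, 2.7],
            [3.3, 3.8, 4.7, 3.7, 4.6],
            [4.1, 4.8, 3.0, 5.5, 2.7],
            [3.6, 4.4, 3.4, 1.9, 6.5],
            [4.8, 2.7, 4.4, 4.4, 3.6],
        ]
    ),
}

# Published diagonal summaries (diagonal %, diagonal + adjacent %).
PUBLISHED_DIAGONALS: dict[str, tuple[float, float]] = {
    "cse_index": (28.5, 65.2),
    "socioeconomic": (31.8, 67.0),
    "education": (24.7, 63.0),
    "connectedness": (28.1, 66.6),
    "housing": (25.1, 63.5),
    "health_services": (16.3, 52.9),
}

# Avoidable deaths and 0-15 populations per quintile (quintile 1 = highest
# risk), 2007 registrations.
MORTALITY_COUNTS: dict[str, dict[str, list[int]]] = {
    "cse_index": {
        "deaths": [240, 175, 189, 163, 114],
        "population": [747511, 759398, 752010, 756553, 757980],
    },
    "socioeconomic": {
        "deaths": [229, 191, 167, 164, 130],
        "population": [750623, 757969, 752355, 756258, 756247],
    },
    "education": {
        "deaths": [235, 164, 188, 153, 141],
        "population": [738789, 766628, 749371, 762797, 755866],
    },
    "connectedness": {
        "deaths": [215, 206, 174, 156, 131],
        "population": [752973, 749644, 760712, 754042, 756081],
    },
    "housing": {
        "deaths": [218, 211, 189, 131, 132],
        "population": [741278, 753022, 765405, 757058, 756688],
    },
    "health_services": {
        "deaths": [195, 166, 159, 166, 195],
        "population": [751604, 749686, 755523, 760827, 755811],
    },
}

# Published chi-square statistics for the mortality contingency tables.  The
# composite-index statistic recomputed from the printed counts is ~49.1, not
# the published 49.9 (the source likely used unrounded estimated deaths); the
# five domain statistics reproduce to one decimal.
PUBLISHED_CHI2: dict[str, float] = {
    "cse_index": 49.9,
    "socioeconomic": 31.2,
    "education": 35.6,
    "connectedness": 28.3,
    "housing": 42.5,
    "health_services": 7.1,
}

# Published per-quintile PPH rate summary (mean, sd, min, max), composite index.
PUBLISHED_PPH_QUINTILE_SUMMARY = {
    1: (35.7, 24.6, 4.4, 193.6),
    2: (24.6, 10.8, 7.1, 83.2),
    3: (24.0, 10.7, 5.4, 108.5),
    4: (22.5, 9.5, 3.5, 75.3),
    5: (20.4, 6.4, 8.9, 45.6),
}

# Published residual-PPH-rate summary by remoteness (mean, sd, min, max, n).
PUBLISHED_RESIDUALS_BY_REMOTENESS = {
    "Major cities": (-2.4, 6.0, -16.4, 47.7, 383),
    "Inner regional": (-0.5, 10.3, -20.4, 90.0, 263),
    "Outer regional": (-0.9, 10.9, -20.5, 39.7, 293),
    "Remote": (8.3, 25.6, -47.2, 140.0, 82),
    "Very remote": (6.8, 29.8, -40.7, 167.4, 91),
}

# Published quadratic fit of area PPH rate on the composite index:
# rate = 0.0071 * index^2 + 21.74 (p < 0.001, r^2 = 0.22).
PUBLISHED_QUADRATIC_COEF = 0.0071
PUBLISHED_QUADRATIC_INTERCEPT = 21.74
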