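"""Index construction: filtering, orientation, domain scores, rank transform,
composite, and population-weighted quintiles."""

import math

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from csehealth.index import (
    build_index,
    composite_index,
    exponential_rank_transform,
    filter_areas,
    orient_indicators,
    score_domain_mean,
    score_domain_pca,
    weighted_quintiles,
)
from csehealth.indicators import (
    CONNECTEDNESS,
    HEALTH_SERVICES,
    HOUSING,
    INDICATOR_NAMES,
    ORIENTATION_OF,
    RATIO_INVERTED,
    domain_indicators,
)
from csehealth.synthetic import SimulationConfig, generate

from conftest import make_area_frame


# ---------------------------------------------------------------- filtering

class TestFilterAreas:
    def test_population_threshold_is_strict(self):
        areas = make_area_frame([29, 30, 500])
        included, excluded = filter_areas(areas)
        assert list(included["area_id"]) == ["A0002", "A0003"]
        assert list(excluded["area_id"]) == ["A0001"]
        assert excluded.iloc[0]["low_population"] and not excluded.iloc[0]["low_response"]

    def test_nonresponse_threshold_is_inclusive(self):
        areas = make_area_frame([30, 40], nonresponse={0: {"overcrowding": 0.80}})
        included, excluded = filter_areas(areas)
        assert list(excluded["area_id"]) == ["A0001"]
        assert excluded.iloc[0]["low_response"] and not excluded.iloc[0]["low_population"]

    def test_both_reasons_recorded(self):
        areas = make_area_frame([10, 40], nonresponse={0: {"gp_ratio": 0.9}})
        _, excluded = filter_areas(areas)
        assert excluded.iloc[0]["low_population"] and excluded.iloc[0]["low_response"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no areas"):
            filter_areas(make_area_frame([]))

    def test_all_excluded_names_both_thresholds(self):
        with pytest.raises(ValueError) as err:
            filter_areas(make_area_frame([5, 10]), min_children=30, max_nonresponse=0.8)
        assert "30" in str(err.value) and "0.8" in str(err.value)


# -------------------------------------------------------------- orientation

def _indicator_frame(rng, n=20):
    data = {"area_id": [f"A{i:04d}" for i in range(n)]}
    for name in INDICATOR_NAMES:
        if ORIENTATION_OF[name] == RATIO_INVERTED:
            data[name] = rng.lognormal(0, 0.4, n)
        else:
            data[name] = rng.uniform(0.01, 0.6, n)
    return pd.DataFrame(data)


class TestOrientation:
    def test_ratio_order_exactly_reversed(self):
        rng = np.random.default_rng(0)
        df = _indicator_frame(rng, 3)
        df["gp_ratio"] = [2.0, 1.0, 0.5]
        out = orient_indicators(df)
        assert list(np.argsort(out["gp_ratio"])) == [0, 1, 2]  # 2.0 -> lowest risk

    def test_proportions_pass_through_bit_identical(self):
        rng = np.random.default_rng(1)
        df = _indicator_frame(rng)
        out = orient_indicators(df)
        for name in INDICATOR_NAMES:
            if ORIENTATION_OF[name] != RATIO_INVERTED:
                assert (out[name].to_numpy() == df[name].to_numpy()).all()

    def test_spearman_plus_or_minus_one(self):
        rng = np.random.default_rng(2)
        df = _indicator_frame(rng, 50)
        out = orient_indicators(df)
        for name in INDICATOR_NAMES:
            rho = spearmanr(df[name], out[name]).statistic
            expected = -1.0 if ORIENTATION_OF[name] == RATIO_INVERTED else 1.0
            assert rho == pytest.approx(expected)

    def test_non_finite_ratio_lists_offending_areas(self):
        rng = np.random.default_rng(3)
        df = _indicator_frame(rng, 4)
        df.loc[2, "dentist_ratio"] = np.nan
        with pytest.raises(ValueError, match="A0002"):
            orient_indicators(df)


# ------------------------------------------------------------ domain scores

class TestDomainScores:
    def test_rank_one_case_tracks_common_signal(self):
        rng = np.random.default_rng(4)
        df = _indicator_frame(rng, 30)
        common = rng.uniform(0.5, 2.0, 30)
        df["gp_ratio"] = common
        df["dentist_ratio"] = 2.0 * common
        score = score_domain_pca(orient_indicators(df), HEALTH_SERVICES)
        oriented_common = -common
        assert abs(np.corrcoef(score, oriented_common)[0, 1]) == pytest.approx(1.0)
        # higher risk (lower access) -> higher score
        assert np.corrcoef(score, oriented_common)[0, 1] > 0

    def test_sign_pinned_by_orientation_rule(self):
        # Whatever sign the eigensolver returns, the score must correlate
        # positively with the mean oriented indicator.
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = orient_indicators(_indicator_frame(rng, 40))
            score = score_domain_pca(df, CONNECTEDNESS)
            vals = df[domain_indicators(CONNECTEDNESS)].to_numpy()
            anchor = ((vals - vals.mean(0)) / vals.std(0, ddof=1)).mean(axis=1)
            assert np.corrcoef(score, anchor)[0, 1] > 0

    def test_matches_brute_force_eigendecomposition(self):
        # 4 areas x 2 indicators, worked by hand through the 2x2 correlation.
        df = pd.DataFrame(
            {
                "area_id": ["A", "B", "C", "D"],
                "gp_ratio": [1.0, 2.0, 3.0, 4.0],
                "dentist_ratio": [0.5, 0.9, 1.1, 2.5],
            }
        )
        oriented = df.copy()
        oriented[["gp_ratio", "dentist_ratio"]] *= -1
        score = score_domain_pca(oriented, HEALTH_SERVICES)

        vals = oriented[["gp_ratio", "dentist_ratio"]].to_numpy()
        std = (vals - vals.mean(0)) / vals.std(0, ddof=1)
        corr = np.corrcoef(std, rowvar=False)
        w, v = np.linalg.eig(corr)  # independent route: eig, not eigh
        lead = v[:, np.argmax(w)]
        expected = std @ lead
        if np.corrcoef(expected, std.mean(1))[0, 1] < 0:
            expected = -expected
        np.testing.assert_allclose(score.to_numpy(), expected, atol=1e-10)

    def test_agrees_with_sklearn_pca(self):
        rng = np.random.default_rng(6)
        df = orient_indicators(_indicator_frame(rng, 60))
        score = score_domain_pca(df, CONNECTEDNESS)
        vals = df[domain_indicators(CONNECTEDNESS)].to_numpy()
        std = (vals - vals.mean(0)) / vals.std(0, ddof=1)
        ref = PCA(n_components=1).fit_transform(std)[:, 0]
        # scores agree up to the sign convention
        agree = min(
            np.abs(score.to_numpy() - ref).max(), np.abs(score.to_numpy() + ref).max()
        )
        assert agree < 1e-8

    def test_zero_variance_indicator_named(self):
        rng = np.random.default_rng(7)
        df = orient_indicators(_indicator_frame(rng, 10))
        df["no_internet_at_home"] = 0.25
        with pytest.raises(ValueError, match="no_internet_at_home"):
            score_domain_pca(df, CONNECTEDNESS)

    def test_housing_directed_to_mean(self):
        rng = np.random.default_rng(8)
        df = orient_indicators(_indicator_frame(rng, 10))
        with pytest.raises(ValueError, match="score_domain_mean"):
            score_domain_pca(df, HOUSING)

    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.30, 0.10, 0.20), (0.0, 0.0, 0.0), (1.0, 1.0, 1.0)],
    )
    def test_housing_mean(self, a, b, expected):
        df = pd.DataFrame(
            {"area_id": ["A"], "rent_stress_30_40": [a], "overcrowding": [b]}
        )
        assert score_domain_mean(df).iloc[0] == pytest.approx(expected)

    def test_housing_mean_symmetric(self):
        df = pd.DataFrame(
            {"area_id": ["A", "B"], "rent_stress_30_40": [0.4, 0.1], "overcrowding": [0.1, 0.4]}
        )
        swapped = df.rename(
            columns={"rent_stress_30_40": "overcrowding", "overcrowding": "rent_stress_30_40"}
        )
        pd.testing.assert_series_equal(score_domain_mean(df), score_domain_mean(swapped))

    def test_pca_score_invariant_to_rescaling_one_indicator(self):
        rng = np.random.default_rng(9)
        df = orient_indicators(_indicator_frame(rng, 50))
        base = score_domain_pca(df, CONNECTEDNESS)
        df2 = df.copy()
        df2["no_motor_vehicle"] = df2["no_motor_vehicle"] * 7.3
        np.testing.assert_allclose(
            base.to_numpy(), score_domain_pca(df2, CONNECTEDNESS).to_numpy(), atol=1e-10
        )


# ------------------------------------------------------ exponential transform

class TestExponentialRankTransform:
    @pytest.mark.parametrize("n", [5, 100, 1154])
    def test_top_rank_is_exactly_100_and_strictly_increasing(self, n):
        rng = np.random.default_rng(n)
        scores = rng.normal(size=n)
        r, x = exponential_rank_transform(scores)
        order = np.argsort(r)
        assert abs(x[order][-1] - 100.0) < 1e-9
        assert np.all(np.diff(x[order]) > 0)
        assert np.all(x > 0)

    def test_half_rank_matches_high_precision_formula(self):
        _, x = exponential_rank_transform([1.0, 2.0])  # N=2 -> R = 0.5, 1.0
        Rsym = sympy.Rational(1, 2)
        expected = sympy.N(
            -23 * sympy.log(1 - Rsym * (1 - sympy.exp(sympy.Rational(-100, 23)))), 30
        )
        assert abs(x[0] - float(expected)) < 1e-12

    def test_limit_at_zero_rank_is_zero(self):
        c = 1 - math.exp(-100 / 23)
        assert -23 * math.log(1 - 0.0 * c) == 0.0

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            exponential_rank_transform([1.0, float("nan")])

    def test_ties_take_consecutive_ranks(self):
        r, x = exponential_rank_transform([1.0, 1.0, 1.0])
        assert sorted(r) == [pytest.approx(k / 3) for k in (1, 2, 3)]
        assert abs(max(x) - 100.0) < 1e-9


# ----------------------------------------------------------------- composite

class TestComposite:
    def _frame(self, rows):
        from csehealth.indicators import DOMAINS

        return pd.DataFrame(rows, columns=[f"X_{d}" for d in DOMAINS])

    def test_constant_row(self):
        assert composite_index(self._frame([[100.0] * 5])).iloc[0] == pytest.approx(100.0)

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(1, 100, size=(20, 5))
        df = self._frame(vals)
        comp = composite_index(df)
        shuffled = self._frame(vals[:, [3, 0, 4, 1, 2]])
        np.testing.assert_allclose(comp, composite_index(shuffled))
        assert (comp >= vals.min(axis=1)).all() and (comp <= vals.max(axis=1)).all()

    def test_missing_domain_named(self):
        df = self._frame([[50.0] * 5]).drop(columns=["X_Housing"])
        with pytest.raises(ValueError, match="Housing"):
            composite_index(df)


# ------------------------------------------------------------------ quintiles

def brute_force_quintiles(basis, weights):
    """Independent enumeration of cumulative-weight intervals (oracle)."""
    items = sorted(basis.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(weights[a] for a, _ in items)
    out = {}
    cum = 0.0
    for aid, _ in items:
        w = weights[aid]
        mid = (cum + cum + w) / 2.0 / total
        k = 1
        while not ((k - 1) / 5 < mid <= k / 5) and k < 5:
            k += 1
        out[aid] = k
        cum += w
    return out


class TestWeightedQuintiles:
    def test_equal_weights_two_per_quintile(self):
        basis = pd.Series(range(10, 0, -1), index=[f"A{i}" for i in range(10)])
        w = pd.Series(1.0, index=basis.index)
        qa = weighted_quintiles(basis, w)
        counts = qa.quintile.value_counts()
        assert (counts == 2).all()
        top2 = basis.nlargest(2).index
        assert (qa.quintile[top2] == 1).all()

    def test_dominant_area_matches_brute_force(self):
        basis = pd.Series([9.0, 5.0, 4.0, 1.0], index=list("ABCD"))
        w = pd.Series([60.0, 20.0, 10.0, 10.0], index=list("ABCD"))
        qa = weighted_quintiles(basis, w)
        expected = brute_force_quintiles(basis.to_dict(), w.to_dict())
        assert qa.quintile.to_dict() == expected
        # the dominant area's midpoint (30%) lands in quintile 2
        assert qa.quintile["A"] == 2

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            ids = [f"A{i:03d}" for i in range(n)]
            basis = pd.Series(rng.normal(size=n), index=ids)
            w = pd.Series(rng.integers(1, 1000, size=n).astype(float), index=ids)
            qa = weighted_quintiles(basis, w)
            assert qa.quintile.to_dict() == brute_force_quintiles(
                basis.to_dict(), w.to_dict()
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_quintile_share_within_atomicity_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        ids = [f"A{i:03d}" for i in range(n)]
        basis = pd.Series(rng.normal(size=n), index=ids)
        w = pd.Series(rng.integers(1, 500, size=n).astype(float), index=ids)
        qa = weighted_quintiles(basis, w)
        total = w.sum()
        shares = w.groupby(qa.quintile).sum() / total
        bound = w.max() / total + 1e-12
        for k in range(1, 6):
            assert abs(shares.get(k, 0.0) - 0.2) <= bound

    def test_zero_total_weight_rejected(self):
        basis = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError, match="weight"):
            weighted_quintiles(basis, pd.Series([0.0, 0.0], index=["A", "B"]))


# ------------------------------------------------------------------ pipeline

class TestEndToEnd:
    def test_noise_free_composite_monotone_in_latent(self):
        ds = generate(SimulationConfig(n_areas=200, seed=21, indicator_noise_sd=0.0))
        res = build_index(ds.areas, ds.indicators)
        z = ds.latent.reindex(res.table.index)
        rho = spearmanr(res.table["composite"], z).statistic
        assert rho == pytest.approx(1.0)

    def test_latent_recovery_exceeds_point_eight(self, recovery_dataset):
        ds = recovery_dataset
        res = build_index(ds.areas, ds.indicators)
        z = ds.latent.reindex(res.table.index)
        from csehealth.association import weighted_pearson

        r = weighted_pearson(res.table["composite"], z, res.quintiles.weights)
        assert r > 0.8

    def test_transform_bounds_hold_everywhere(self, small_dataset):
        res = build_index(small_dataset.areas, small_dataset.indicators)
        from csehealth.indicators import DOMAINS

        for d in DOMAINS:
            col = res.table[f"X_{d}"]
            assert (col > 0).all() and (col <= 100 + 1e-9).all()
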