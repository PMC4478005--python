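"""ANCOVA filter, CAP ordination, permutation tests and variance summaries."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from otomorph import (
    ValidationError,
    ancova_filter,
    cap,
    permutation_anova,
    variance_age_regression,
    within_variance,
)


class TestAncovaFilter:
    def test_constructed_interaction_is_dropped(self, rng):
        n = 30
        group = np.repeat(["A", "B", "C"], n)
        length = rng.uniform(20, 35, size=3 * n)
        beta = {"A": 0.1, "B": 0.5, "C": -0.2}
        coef = np.array([beta[g] for g in group]) * length
        report = ancova_filter(coef[:, None], length, group)
        assert report.dropped and report.dropped[0][0] == 0

    def test_constant_coefficient_is_kept(self, rng):
        group = np.repeat(["A", "B"], 20)
        length = rng.uniform(20, 35, size=40)
        report = ancova_filter(np.full((40, 1), 2.0), length, group)
        assert report.kept == [0]

    def test_pvalue_matches_statsmodels_nested_f(self, rng):
        import statsmodels.api as sm
        import pandas as pd
        from statsmodels.formula.api import ols

        n = 30
        group = np.repeat(["A", "B", "C"], n)
        length = rng.uniform(20, 35, size=3 * n)
        coef = (
            0.3 * length
            + np.array([{"A": 0, "B": 1.0, "C": -1}[g] for g in group])
            + np.array([{"A": 0, "B": 0.04, "C": 0}[g] for g in group]) * length
            + rng.normal(0, 0.5, size=3 * n)
        )
        report = ancova_filter(coef[:, None], length, group, alpha=0.05)
        df = pd.DataFrame({"y": coef, "length": length, "pop": group})
        full = ols("y ~ length * pop", df).fit()
        red = ols("y ~ length + pop", df).fit()
        oracle = full.compare_f_test(red)[1]
        assert report.p_values[0] == pytest.approx(oracle, abs=1e-8)

    def test_null_drop_rate_matches_alpha(self, rng):
        n = 30
        group = np.repeat(["A", "B"], n)
        length = rng.uniform(20, 35, size=2 * n)
        X = rng.normal(size=(2 * n, 1000)) + 0.2 * length[:, None]
        report = ancova_filter(X, length, group, alpha=0.05)
        rate = len(report.dropped) / 1000
        assert 0.032 <= rate <= 0.068  # binomial 99% interval at p=0.05, n=1000

    def test_small_population_excluded_with_warning(self, rng):
        group = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 2)
        length = rng.uniform(20, 35, size=22)
        with pytest.warns(UserWarning, match="C"):
            ancova_filter(rng.normal(size=(22, 2)), length, group)


class TestCAP:
    def test_two_separated_clouds(self, rng):
        a = rng.normal(0, 0.3, size=(20, 5)) + np.array([5, 0, 0, 0, 0])
        b = rng.normal(0, 0.3, size=(20, 5)) - np.array([5, 0, 0, 0, 0])
        res = cap(np.vstack([a, b]), ["A"] * 20 + ["B"] * 20, n_perm=0)
        assert res.group_centroids.shape[1] == 1  # two groups -> one axis
        c = res.group_centroids[:, 0]
        assert c[0] * c[1] < 0
        spread = res.site_scores[:20, 0].std() + res.site_scores[20:, 0].std()
        assert abs(c[0] - c[1]) > spread

    def test_null_pseudo_f_near_one(self, rng):
        fs = []
        for _ in range(200):
            X = rng.normal(size=(24, 5))
            group = rng.permutation(np.repeat(["A", "B", "C"], 8))
            res = cap(X, group, n_perm=0)
            fs.append(res.pseudo_F)
            assert res.constrained_inertia / res.total_inertia < 0.5
        assert 0.8 < np.mean(fs) < 1.3

    def test_covariate_on_first_principal_direction(self, rng):
        X = rng.normal(size=(30, 6)) * np.array([4, 2, 1, 0.5, 0.3, 0.1])
        Xc = X - X.mean(axis=0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        pc1 = U[:, 0] * s[0]
        res = cap(X, ["A", "B", "C"] * 10, covariate=pc1, n_perm=0)
        assert res.conditional_inertia == pytest.approx(s[0] ** 2, abs=1e-8)

    def test_inertia_conservation(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 25))
            X = rng.normal(size=(n, int(rng.integers(3, 8))))
            group = rng.choice(["A", "B", "C"], size=n)
            if len(set(group)) < 2:
                continue
            cov = rng.normal(size=n)
            res = cap(X, group, covariate=cov, n_perm=0)
            total = res.conditional_inertia + res.constrained_inertia + res.residual_inertia
            assert total == pytest.approx(res.total_inertia, abs=1e-9 * max(1, res.total_inertia))

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValidationError):
            cap(rng.normal(size=(10, 3)), ["A"] * 10)


def _oracle_permanova_p(X, group, tol=1e-12):
    """Exhaustive pseudo-F enumeration straight from the distance matrix
    (Gower identity), independent of the ordination code path."""
    D2 = squareform(pdist(X)) ** 2
    n = X.shape[0]
    labels = sorted(set(group))
    k = len(labels)

    def F_of(order):
        g = np.asarray(group)[list(order)]
        ss_total = D2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for lab in labels:
            idx = np.flatnonzero(g == lab)
            ss_within += D2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
        ssb = ss_total - ss_within
        return (ssb / (k - 1)) / (ss_within / (n - k))

    F_obs = F_of(range(n))
    count = total = 0
    for order in itertools.permutations(range(n)):
        count += F_of(order) >= F_obs - tol
        total += 1
    return count / total


class TestPermutationAnova:
    def test_duplicated_groups_have_no_signal(self, rng):
        base = rng.normal(size=(6, 4))
        X = np.vstack([base, base])
        group = ["A"] * 6 + ["B"] * 6
        res = permutation_anova(X, group, n_perm=199, seed=1)
        assert res["pseudo_F"] == pytest.approx(0.0, abs=1e-9)
        assert res["p_value"] > 0.5

    def test_exhaustive_matches_exact_enumeration(self, rng):
        X = rng.normal(size=(6, 3))
        X[:3] += 1.0
        group = ["A"] * 3 + ["B"] * 3
        res = permutation_anova(X, group, method="exhaustive")
        assert res["p_value"] == pytest.approx(_oracle_permanova_p(X, group), abs=1e-12)

    def test_strong_separation_attains_minimum_p(self, rng):
        X = rng.normal(0, 0.05, size=(20, 3))
        X[:10] += 50.0
        group = ["A"] * 10 + ["B"] * 10
        res = permutation_anova(X, group, n_perm=999, seed=2)
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValidationError):
            permutation_anova(rng.normal(size=(8, 2)), ["A"] * 8, n_perm=199)

    def test_contrast_pools_populations(self, rng):
        X = rng.normal(size=(30, 4))
        X[:10] += 3.0  # population P1 differs
        group = np.repeat(["P1", "P2", "P3"], 10)
        contrast = {"P1": "focal", "P2": "rest", "P3": "rest"}
        res = permutation_anova(X, group, contrast=contrast, n_perm=999, seed=3)
        assert res["df"][0] == 1
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_contrast_excludes_unmapped_populations(self, rng):
        X = rng.normal(size=(30, 4))
        group = np.repeat(["P1", "P2", "P3"], 10)
        res = permutation_anova(
            X, group, contrast={"P1": "a", "P2": "b"}, n_perm=199, seed=3
        )
        assert set(res["groups"]) == {"a", "b"}


class TestWithinVariance:
    def test_identical_specimens_give_zero(self):
        X = np.ones((4, 3))
        table = within_variance(X, ["A"] * 4, ["3-5"] * 4)
        assert table["variance"].iloc[0] == 0.0

    def test_two_point_hand_value(self):
        # d^2 = 4, n = 2 -> 4 / (2*1) = 2, the 1-D sample variance
        table = within_variance(np.array([[0.0], [2.0]]), ["A", "A"], ["3-5", "3-5"])
        assert table["variance"].iloc[0] == pytest.approx(2.0)

    def test_equals_pairwise_distance_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        table = within_variance(X, ["A"] * 20, ["3-5"] * 20)
        d2 = pdist(X) ** 2
        oracle = d2.sum() / (20 * 19)
        assert table["variance"].iloc[0] == pytest.approx(oracle, abs=1e-10)

    def test_small_cells_are_omitted(self, rng):
        X = rng.normal(size=(5, 2))
        table = within_variance(
            X, ["A", "A", "A", "B", "B"], ["3-5", "3-5", "6-8", "3-5", "3-5"]
        )
        cells = set(zip(table["population_id"], table["age_group"]))
        assert ("A", "6-8") not in cells
        assert ("A", "3-5") in cells and ("B", "3-5") in cells


class TestVarianceAgeRegression:
    def test_noiseless_line_recovers_slope(self):
        age = np.arange(3, 13, dtype=float)
        disp = 5.0 - 0.25 * age
        slope, p = variance_age_regression(disp, age)
        assert slope == pytest.approx(-0.25, abs=1e-12)
        assert p < 1e-10

    def test_two_points_interpolate(self):
        slope, p = variance_age_regression([1.0, 2.0], [3.0, 5.0])
        assert slope == pytest.approx(0.5)
        assert np.isnan(p)

    def test_constant_age_rejected(self):
        with pytest.raises(ValidationError):
            variance_age_regression([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])

    def test_null_p_values_are_uniform(self, rng):
        ps = []
        for _ in range(500):
            age = np.tile(np.arange(3, 13), 2).astype(float)
            disp = rng.normal(size=age.size)
            ps.append(variance_age_regression(disp, age)[1])
        # rejection rate at alpha=0.05 within the binomial 99.9% interval
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= rate <= 0.085
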