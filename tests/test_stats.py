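"""Group statistics: Mann-Whitney, CV AUC, DeLong, Bonferroni, Spearman, Youden."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from perfquant.errors import ParameterError, StratificationError
from perfquant.stats import (
    bonferroni,
    compare_auc,
    cv_feature_auc,
    feature_stat_table,
    mann_whitney,
    spearman_matrix,
    youden_threshold,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def mw_exact_p(a, b):
    """Exact two-sided Mann-Whitney p by full permutation enumeration."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    idx = range(len(pooled))

    def u_stat(sel):
        x = pooled[list(sel)]
        y = np.delete(pooled, list(sel))
        return sum(np.sum(xi > y) + 0.5 * np.sum(xi == y) for xi in x)

    u_obs = u_stat(range(n1))
    mu = n1 * (len(pooled) - n1) / 2.0
    count = total = 0
    for sel in combinations(idx, n1):
        total += 1
        if abs(u_stat(sel) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def auc_fast(scores, y):
    """Rank-based AUC (ties handled by midranks)."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n1 = int(np.sum(y))
    n0 = len(y) - n1
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


class TestMannWhitney:
    def test_separated_groups_u_zero_and_exact_p(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, p = mann_whitney(a, b)
        assert u == 0.0
        assert mw_exact_p(np.array(a), np.array(b)) == pytest.approx(0.1)
        assert p == pytest.approx(0.1, abs=0.02)

    def test_identical_multisets_no_separation(self):
        a = [1.0, 2.0, 2.0, 5.0]
        _, p = mann_whitney(a, a)
        assert p >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0, 2.0, 3.0])

    def test_swap_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 6)
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1], abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 5), (4, 4), (5, 6), (7, 7)])
    def test_small_samples_agree_with_exact_enumeration(self, n1, n2):
        """Untied small-sample p within 0.02 of the permutation oracle."""
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(6):
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(0, 2), 1, n2)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(mw_exact_p(a, b), abs=0.02)

    def test_tied_small_samples_use_corrected_approximation(self):
        """With ties the tie-corrected approximation stays close to the
        permutation oracle (the exact null is unavailable under ties)."""
        rng = np.random.default_rng(8)
        for _ in range(6):
            a = np.round(rng.normal(0, 1, 6), 0)
            b = np.round(rng.normal(1.0, 1, 7), 0)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(mw_exact_p(a, b), abs=0.06)


class TestCvFeatureAuc:
    def test_perfect_separation(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = cv_feature_auc(x, y, k=10, seed=0)
        assert res.auc_mean == 1.0

    def test_null_feature_near_half(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        res = cv_feature_auc(x, y, k=10, seed=0)
        assert 0.45 <= res.auc_mean <= 0.55

    def test_label_inversion_handled_by_orientation(self):
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0, 1, 60), rng.normal(1.2, 1, 60)]
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        a = cv_feature_auc(x, y, k=10, seed=1).auc_mean
        b = cv_feature_auc(x, 1 - y, k=10, seed=1).auc_mean
        assert a == pytest.approx(b, abs=0.02)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        x = np.r_[rng.normal(0, 1, 40), rng.normal(1, 1, 40)]
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        a = cv_feature_auc(x, y, k=8, seed=2)
        b = cv_feature_auc(np.exp(3 * x), y, k=8, seed=2)
        assert a.auc_mean == pytest.approx(b.auc_mean, abs=1e-12)
        assert a.fold_aucs == b.fold_aucs

    def test_too_few_per_class(self):
        with pytest.raises(StratificationError):
            cv_feature_auc(np.arange(12.0), np.r_[np.zeros(8, int), np.ones(4, int)], k=10)

    def test_ci_clipped_and_ordered(self):
        rng = np.random.default_rng(11)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        res = cv_feature_auc(x, y, k=10, seed=0)
        lo, hi = res.ci95
        assert 0.0 <= lo <= res.auc_mean <= hi <= 1.0


class TestCompareAuc:
    def test_identical_features(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        z, p = compare_auc(x, x.copy(), y)
        assert z == 0.0 and p == 1.0

    def test_informative_beats_noise(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        good = np.r_[rng.normal(0, 0.2, 100), rng.normal(3, 0.2, 100)]
        noise = rng.normal(size=200)
        _, p = compare_auc(good, noise, y)
        assert p < 0.001

    def test_constant_feature_rejected(self):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.raises(ParameterError):
            compare_auc(np.ones(20), np.arange(20.0), y)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_paired_bootstrap_oracle(self, seed):
        """DeLong p within 0.03 of a 2000-resample paired bootstrap z-test."""
        rng = np.random.default_rng(seed)
        n = 40
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        f1 = np.r_[rng.normal(0, 1, n), rng.normal(1.0, 1, n)]
        f2 = 0.6 * f1 + rng.normal(0, 1, 2 * n)
        _, p = compare_auc(f1, f2, y)
        diffs = []
        idx0, idx1 = np.nonzero(y == 0)[0], np.nonzero(y == 1)[0]
        for _ in range(2000):
            b = np.r_[rng.choice(idx0, n), rng.choice(idx1, n)]
            diffs.append(auc_fast(f1[b], y[b]) - auc_fast(f2[b], y[b]))
        diffs = np.asarray(diffs)
        obs = auc_fast(f1, y) - auc_fast(f2, y)
        z_boot = obs / diffs.std(ddof=1)
        from scipy.stats import norm

        p_boot = 2 * norm.sf(abs(z_boot))
        assert p == pytest.approx(p_boot, abs=0.03)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,expected", [(0.0005, 0.022), (0.5, 1.0), (1 / 44, 1.0)]
    )
    def test_arithmetic_at_family_size_44(self, p, expected):
        assert bonferroni([p], m=44)[0] == pytest.approx(expected)

    def test_never_decreases_and_idempotent_at_cap(self):
        p = np.array([1e-6, 0.01, 0.2, 0.9])
        adj = bonferroni(p, m=44)
        assert np.all(adj >= p)
        assert np.all(bonferroni(adj, m=44) >= adj)
        assert bonferroni([0.9], m=44)[0] == 1.0

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni(np.full(50, 0.01), m=44)


class TestSpearman:
    def test_monotone_relations(self):
        x = np.linspace(-2, 2, 20)
        table = pd.DataFrame({"x": x, "double": 2 * x, "negcube": -(x**3)})
        rho, _ = spearman_matrix(table)
        assert rho.loc["x", "double"] == pytest.approx(1.0)
        assert rho.loc["x", "negcube"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        table["b"] = np.round(table["b"], 1)  # introduce ties
        rho, _ = spearman_matrix(table)
        for i in "abc":
            for j in "abc":
                ri, rj = rankdata(table[i]), rankdata(table[j])
                expected = np.corrcoef(ri, rj)[0, 1]
                assert rho.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({"x": np.arange(8.0), "c": np.ones(8)})
        rho, pv = spearman_matrix(table)
        assert np.isnan(rho.loc["x", "c"]) and np.isnan(pv.loc["x", "c"])

    def test_minimum_subjects(self):
        with pytest.raises(ParameterError):
            spearman_matrix(pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]}))


class TestYouden:
    def test_separable_groups(self):
        values = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = youden_threshold(values, labels)
        assert 3.0 < res.threshold < 7.0
        assert res.sensitivity == res.specificity == res.accuracy == 1.0

    def test_constant_values_degenerate(self):
        res = youden_threshold(np.ones(10), np.r_[np.zeros(5, int), np.ones(5, int)])
        assert res.sensitivity + res.specificity == pytest.approx(1.0)

    def test_orientation_gives_nonnegative_j(self):
        # positive class has LOWER values (like PSR)
        values = np.r_[np.full(6, 5.0), np.full(6, 1.0)]
        labels = np.r_[np.zeros(6, int), np.ones(6, int)]
        res = youden_threshold(values, labels)
        assert res.direction == -1
        assert res.sensitivity + res.specificity - 1 >= 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(0, 1, 24), 1)
        labels = (rng.random(24) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = youden_threshold(values, labels)
        best_j = -np.inf
        uniq = np.sort(np.unique(values))
        for thr in (uniq[:-1] + uniq[1:]) / 2:
            for direction in (+1, -1):
                pred = (values > thr) if direction == 1 else (values < thr)
                sens = (pred & (labels == 1)).sum() / labels.sum()
                spec = (~pred & (labels == 0)).sum() / (1 - labels).sum()
                best_j = max(best_j, sens + spec - 1)
        assert res.sensitivity + res.specificity - 1 == pytest.approx(best_j, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_reported_operating_point_reproduces(self, seed):
        """Re-applying the returned threshold reproduces sens/spec exactly."""
        rng = np.random.default_rng(seed + 10)
        values = rng.normal(0, 1, 30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        res = youden_threshold(values, labels)
        pred = (values > res.threshold) if res.direction == 1 else (values < res.threshold)
        assert (pred & (labels == 1)).sum() / labels.sum() == pytest.approx(res.sensitivity)
        assert (~pred & (labels == 0)).sum() / (1 - labels).sum() == pytest.approx(
            res.specificity
        )


def test_feature_stat_table_schema():
    rng = np.random.default_rng(0)
    n = 26
    table = pd.DataFrame({
        "f1": np.r_[rng.normal(0, 1, 13), rng.normal(1.5, 1, 13)],
        "f2": rng.normal(size=n),
        "label": ["astrocytoma"] * 13 + ["oligodendroglioma"] * 13,
    })
    rows = feature_stat_table(table, ["f1", "f2"], k=5, seed=0)
    assert list(rows.feature) == ["f1", "f2"]
    assert (rows.p_bonferroni >= rows.p_raw).all()
    assert rows.auc_mean.between(0, 1).all()
    assert (rows.sensitivity.between(0, 1) & rows.specificity.between(0, 1)).all()
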