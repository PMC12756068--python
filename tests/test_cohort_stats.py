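"""Statistical battery: exact oracles, identities, and calibration checks."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from frocdwi import (auc_mann_whitney, combined_model_auc, delong_test,
                     icc_two_way_random, kruskal_wallis, mann_whitney_u,
                     pairwise_bonferroni, roc_analysis, spearman_rho)
from frocdwi.cohort_stats import delong_variance


def brute_force_mwu_p(x, y):
    """Exhaustive-permutation two-sided p via pairwise-comparison counting."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size

    def u_of(a, b):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    center = n1 * (pooled.size - n1) / 2
    obs = abs(u_of(x, y) - center)
    hits = total = 0
    for idx in combinations(range(pooled.size), n1):
        sel = np.zeros(pooled.size, bool)
        sel[list(idx)] = True
        total += 1
        if abs(u_of(pooled[sel], pooled[~sel]) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_disjoint_groups_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("x,y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 2, 2], [2, 3, 4]),
        ([1, 1, 2, 2], [1, 2, 2]),
        ([5.0], [1.0, 2.0, 3.0]),
        ([1, 3, 5, 7], [2, 4, 6, 8]),
    ])
    def test_matches_exhaustive_permutation_oracle(self, x, y):
        res = mann_whitney_u(x, y)
        assert res.p_value == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.extra["U_x"] == pytest.approx(4.5)   # n^2/2
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    def test_large_sample_uses_asymptotic(self, rng):
        res = mann_whitney_u(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        assert res.extra["method"] == "asymptotic"
        assert 0 <= res.p_value <= 1


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h_on_ranks_1_to_6(self):
        # ranks 1..6, group mean ranks 1.5/3.5/5.5, grand 3.5:
        # H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2) = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7, rel=1e-12)

    def test_pairwise_bonferroni_definition(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        pairs = pairwise_bonferroni(groups)
        assert len(pairs) == 3
        for res in pairs.values():
            assert res.adjusted_p == pytest.approx(min(1.0, 3 * res.p_value))
            assert res.adjusted_p >= res.p_value


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_rho([1, 2, 3, 4, 5], [10, 20, 40, 80, 160]).statistic
        down = spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).statistic
        assert up == pytest.approx(1.0, abs=1e-12)
        assert down == pytest.approx(-1.0, abs=1e-12)

    def test_tied_data_against_manual_ranks(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 5]
        rank_x = np.array([1.0, 2.5, 2.5, 4.0])   # manual midranks
        rank_y = np.array([1.0, 3.0, 2.0, 4.0])
        want = np.corrcoef(rank_x, rank_y)[0, 1]
        assert spearman_rho(x, y).statistic == pytest.approx(want, rel=1e-12)

    def test_strength_bands(self):
        res = spearman_rho([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.extra["strength"] == "good"

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestIcc:
    def test_identical_readers(self):
        v = np.arange(10.0)
        res = icc_two_way_random(np.column_stack([v, v]))
        assert res.statistic == pytest.approx(1.0)

    def test_constant_bias_penalized(self):
        v = np.arange(10.0)
        res = icc_two_way_random(np.column_stack([v, v + 5.0]))
        assert res.statistic < 1.0

    def test_matches_manual_anova_decomposition(self):
        r = np.array([[9, 2], [1, 10], [8, 9], [2, 6], [7, 8], [2, 8]], float)
        n, k = r.shape
        grand = r.mean()
        msr = k * ((r.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((r.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sst = ((r - grand) ** 2).sum()
        mse = (sst - (n - 1) * msr / k * k - (k - 1) * msc / n * n) / ((n - 1) * (k - 1))
        want = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_two_way_random(r)
        assert res.statistic == pytest.approx(want, abs=1e-10)

    def test_too_few_lesions_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way_random(np.ones((4, 2)))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        res = roc_analysis(scores, labels, positive_low=False)
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert 3 < res.cutoff < 10

    def test_auc_equals_sklearn_on_seeded_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.integers(20, 60)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            scores = rng.normal(labels * 0.8, 1.0)
            got = auc_mann_whitney(scores, labels)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_identity_with_u_statistic(self, rng):
        """AUC = U_pos / (n_pos * n_neg) exactly, ties included."""
        labels = rng.random(40) < 0.5
        scores = np.round(rng.normal(labels * 1.0, 1.0), 1)  # force ties
        u_x = mann_whitney_u(scores[labels], scores[~labels]).extra["U_x"]
        n1, n0 = labels.sum(), (~labels).sum()
        assert auc_mann_whitney(scores, labels) == pytest.approx(u_x / (n1 * n0))

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        labels = np.repeat([False, True], 500)
        res = roc_analysis(rng.normal(0, 1, 1000), labels, positive_low=False)
        assert 0.45 <= res.auc <= 0.55

    def test_auto_orientation_for_low_positive(self, rng):
        benign = rng.normal(1400, 280, 50)
        malignant = rng.normal(820, 120, 109)
        scores = np.concatenate([benign, malignant])
        labels = np.repeat([False, True], [50, 109])
        res = roc_analysis(scores, labels)
        assert res.positive_low is True
        assert res.auc > 0.9

    def test_monotone_transform_invariance(self, rng):
        labels = rng.random(80) < 0.5
        scores = rng.normal(labels * 1.0, 1.0)
        a = roc_analysis(scores, labels, positive_low=False).auc
        b = roc_analysis(np.exp(scores), labels, positive_low=False).auc
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [True, True])


class TestDeLong:
    def _fixture(self, seed=5, n=40):
        rng = np.random.default_rng(seed)
        labels = np.repeat([False, True], n // 2)
        a = rng.normal(labels * 1.0, 1.0)
        b = 0.5 * a + rng.normal(labels * 0.8, 1.0)
        return a, b, labels

    def test_identical_scores(self):
        a, _, labels = self._fixture()
        res = delong_test(a, a, labels)
        assert res.p_value == 1.0
        assert res.extra["auc_diff"] == 0.0

    def test_monotone_transform_gives_equal_aucs(self):
        a, _, labels = self._fixture()
        res = delong_test(a, a**3 + 5, labels)  # odd power: monotone
        assert res.extra["auc_diff"] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_variance_against_paired_bootstrap(self):
        a, b, labels = self._fixture()
        res = delong_test(a, b, labels)
        rng = np.random.default_rng(17)
        n = labels.size
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if labels[idx].all() or not labels[idx].any():
                continue
            diffs.append(auc_mann_whitney(a[idx], labels[idx])
                         - auc_mann_whitney(b[idx], labels[idx]))
        ratio = res.extra["var"] / np.var(diffs, ddof=1)
        assert 0.7 <= ratio <= 1.4

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2, 3], [1, 2], [True, False, True])


class TestCombinedModel:
    def _data(self, seed=2, n=120):
        rng = np.random.default_rng(seed)
        labels = rng.random(n) < 0.5
        x1 = rng.normal(labels * 1.0, 1.0)
        x2 = rng.normal(labels * 0.6, 1.0)
        return x1, x2, labels

    def test_single_metric_reduces_to_plain_roc(self):
        x1, _, labels = self._data()
        combined = combined_model_auc(x1[:, None], labels)
        single = roc_analysis(x1, labels)
        assert combined.auc == pytest.approx(single.auc, abs=1e-12)

    def test_duplicated_metric_changes_nothing(self):
        x1, _, labels = self._data()
        a = combined_model_auc(x1[:, None], labels).auc
        b = combined_model_auc(np.column_stack([x1, x1]), labels).auc
        assert b == pytest.approx(a, abs=1e-9)

    def test_two_feature_combination_beats_singles(self):
        x1, x2, labels = self._data()
        X = np.column_stack([x1, x2])
        combined = combined_model_auc(X, labels).auc
        singles = [roc_analysis(x, labels).auc for x in (x1, x2)]
        assert combined >= max(singles) - 0.01

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            combined_model_auc(np.ones((10, 2)), np.repeat([True, False], 5))
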