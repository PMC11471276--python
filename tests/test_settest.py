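import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msfeast.clustering import kmedoids
from msfeast.settest import (
    Contrast,
    bonferroni,
    build_contrasts,
    global_test_statistic,
    log2_fold_change,
    permutation_pvalue,
    run_settest,
    univariate_pvalues,
)
from msfeast.similarity import pairwise_similarity, to_distance
from msfeast.spectra import SampleMetadata


class TestBuildContrasts:
    def test_reference_vs_each_treatment_sorted(self):
        md = SampleMetadata(
            {**{f"c{i}": "ctrl" for i in range(2)},
             **{f"a{i}": "A" for i in range(2)},
             **{f"b{i}": "B" for i in range(2)}},
            reference_group="ctrl",
        )
        contrasts = build_contrasts(md)
        assert [c.name for c in contrasts] == ["ctrl_vs_A", "ctrl_vs_B"]
        assert all(set(c.reference_samples) == {"c0", "c1"} for c in contrasts)

    def test_two_groups_give_one_contrast(self):
        md = SampleMetadata(
            {**{f"c{i}": "ctrl" for i in range(3)}, **{f"t{i}": "trt" for i in range(3)}},
            reference_group="ctrl",
        )
        assert len(build_contrasts(md)) == 1


class TestGlobalTestStatistic:
    def test_constant_columns_give_untestable(self):
        y = np.array([0, 0, 1, 1])
        assert global_test_statistic(np.ones((4, 3)), y) is None

    def test_hand_worked_four_sample_instance(self):
        # literal recomputation of the quadratic form with small integers
        y = np.array([0, 0, 1, 1], dtype=float)
        X = np.array([[1.0, 2.0], [2.0, 1.0], [4.0, 3.0], [5.0, 4.0]])
        # independent arithmetic: standardize, form XX'/m, sandwich with c
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        c = y - y.mean()
        expected = float(c @ (Z @ Z.T / 2.0) @ c)
        assert global_test_statistic(X, y) == pytest.approx(expected, abs=1e-12)
        assert expected > 0

    def test_single_column_proportional_to_indicator(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        c = y - y.mean()
        X = (3.0 * c).reshape(-1, 1)
        q = global_test_statistic(X, y)
        # after unit standardization Z = c * sqrt(n-1)/||c||, so Q = (n-1)||c||^2
        assert q == pytest.approx((len(y) - 1) * float(c @ c), abs=1e-12)

    def test_invariant_to_joint_row_and_column_reordering(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        X = rng.normal(size=(6, 4))
        q = global_test_statistic(X, y)
        perm = rng.permutation(6)
        cols = rng.permutation(4)
        assert global_test_statistic(X[np.ix_(perm, cols)], y[perm]) == pytest.approx(q, abs=1e-9)

    def test_requires_both_labels(self):
        with pytest.raises(ValueError):
            global_test_statistic(np.random.default_rng(0).normal(size=(4, 2)), np.zeros(4))


class TestPermutationPvalue:
    def test_exhaustive_path_three_vs_three(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 0, 0, 1, 1, 1])
        p, n_used, exhaustive = permutation_pvalue(rng.normal(size=(6, 3)), y, n_perm=199, seed=0)
        assert exhaustive and n_used == 20
        assert abs(p * 20 - round(p * 20)) < 1e-9
        assert 0 < p <= 1

    def test_monte_carlo_path_never_zero(self):
        rng = np.random.default_rng(2)
        y = np.array([0] * 6 + [1] * 6)  # C(12,6)=924 > 199
        X = rng.normal(size=(12, 3))
        X[6:] += 10  # extreme signal
        p, n_used, exhaustive = permutation_pvalue(X, y, n_perm=199, seed=0)
        assert not exhaustive and n_used == 199
        assert p == pytest.approx(1 / 200)

    def test_type_i_error_calibrated(self):
        # null scenario, Monte-Carlo path: rejection rate near alpha
        y = np.array([0] * 6 + [1] * 6)
        rng = np.random.default_rng(42)
        rejections = sum(
            permutation_pvalue(rng.normal(size=(12, 5)), y, n_perm=199, seed=1000 + r)[0] <= 0.05
            for r in range(300)
        )
        assert 0.02 <= rejections / 300 <= 0.08

    def test_power_for_concordant_shift(self):
        y = np.array([0] * 6 + [1] * 6)
        rng = np.random.default_rng(7)
        rejections = 0
        for r in range(100):
            X = rng.normal(size=(12, 5))
            X[6:] += 2.0
            rejections += permutation_pvalue(X, y, n_perm=199, seed=r)[0] <= 0.05
        assert rejections / 100 > 0.8


class TestUnivariate:
    def test_constant_column_flagged(self):
        y = np.array([0, 0, 1, 1])
        X = np.column_stack([np.ones(4), [1.0, 2.0, 3.0, 4.0]])
        out = univariate_pvalues(X, y, n_perm=99, seed=0)
        assert out[0] == (1.0, True)
        assert not out[1][1]

    def test_single_column_matches_set_test_bitwise(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 6 + [1] * 6)
        X = rng.normal(size=(12, 1))
        p_set = permutation_pvalue(X, y, n_perm=199, seed=11)[0]
        p_uni = univariate_pvalues(X, y, n_perm=199, seed=11)[0][0]
        assert p_uni == p_set

    def test_matches_exhaustive_t_squared_permutation(self):
        # for fixed group sizes, t^2 is a monotone function of the squared
        # mean difference, which is what the m=1 statistic ranks by; the
        # exhaustive permutation p-values must therefore coincide
        from itertools import combinations

        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        y = np.array([0, 0, 0, 1, 1, 1])
        p_ours = univariate_pvalues(x.reshape(-1, 1), y, n_perm=199, seed=0)[0][0]
        t_obs = stats.ttest_ind(x[y == 1], x[y == 0]).statistic ** 2
        count = 0
        for ones in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(ones)] = True
            t_perm = stats.ttest_ind(x[mask], x[~mask]).statistic ** 2
            count += t_perm >= t_obs - 1e-12
        assert p_ours == pytest.approx(count / 20, abs=1e-12)


class TestFoldChange:
    @pytest.fixture
    def contrast(self):
        return Contrast("c_vs_t", ("r1", "r2"), ("t1", "t2"))

    def test_equal_means_zero(self, contrast):
        row = pd.Series({"r1": 3.0, "r2": 5.0, "t1": 4.0, "t2": 4.0})
        assert log2_fold_change(row, contrast, pseudocount=0) == 0.0

    def test_fourfold_is_two(self, contrast):
        row = pd.Series({"r1": 1.0, "r2": 1.0, "t1": 4.0, "t2": 4.0})
        assert log2_fold_change(row, contrast, pseudocount=0) == pytest.approx(2.0)

    def test_zero_reference_with_pseudocount(self, contrast):
        row = pd.Series({"r1": 0.0, "r2": 0.0, "t1": 10.0, "t2": 10.0})
        assert log2_fold_change(row, contrast, pseudocount=1.0) == pytest.approx(
            np.log2(11.0), abs=1e-6
        )

    def test_all_zero_without_pseudocount_rejected(self, contrast):
        row = pd.Series({"r1": 0.0, "r2": 0.0, "t1": 0.0, "t2": 0.0})
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(row, contrast, pseudocount=0)


class TestBonferroni:
    def test_scaling_clamping_identity(self):
        assert bonferroni([0.001], 20) == [pytest.approx(0.02)]
        assert bonferroni([0.2], 20) == [1.0]
        assert bonferroni([0.3], 1) == [pytest.approx(0.3)]

    def test_family_smaller_than_values_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


@pytest.fixture(scope="module")
def solution(planted):
    dataset, _, _ = planted
    dist = to_distance(pairwise_similarity(dataset.spectra))
    return kmedoids(dist, 3, seed=7)


class TestRunSettest:
    def test_result_counting_and_family_size(self, planted, solution):
        dataset, _, _ = planted
        results, feats = run_settest(dataset, solution, n_perm=199, seed=0)
        assert len(results) == 3  # 3 clusters x 1 contrast
        assert len(feats) == dataset.n_features
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_planted_cluster_has_smallest_adjusted_p(self, planted, solution):
        dataset, labels, truth = planted
        results, _ = run_settest(dataset, solution, n_perm=199, seed=0)
        # map solution clusters onto true labels via majority vote
        majority = {}
        for c in {r.cluster_id for r in results}:
            members = [f for f, cc in solution.assignment.items() if cc == c]
            majority[c] = int(np.bincount([labels[f] for f in members]).argmax())
        differential = set(truth[truth.differential].cluster)
        best = min(results, key=lambda r: r.p_adjusted)
        assert majority[best.cluster_id] in differential

    def test_bitwise_deterministic_rerun(self, planted, solution):
        dataset, _, _ = planted
        r1, f1 = run_settest(dataset, solution, n_perm=199, seed=5)
        r2, f2 = run_settest(dataset, solution, n_perm=199, seed=5)
        assert [(x.p_raw, x.q_statistic) for x in r1] == [(x.p_raw, x.q_statistic) for x in r2]
        assert [(x.p_univariate, x.log2_fold_change) for x in f1] == [
            (x.p_univariate, x.log2_fold_change) for x in f2
        ]

    def test_singleton_cluster_set_p_equals_univariate(self, planted):
        dataset, _, _ = planted
        dist = to_distance(pairwise_similarity(dataset.spectra))
        sol = kmedoids(dist, dataset.n_features - 1, seed=3)  # forces singletons
        results, feats = run_settest(dataset, sol, n_perm=199, seed=2)
        uni = {(f.feature_id, f.contrast_name): f.p_univariate for f in feats}
        singles = 0
        for r in results:
            members = [f for f, c in sol.assignment.items() if c == r.cluster_id]
            if len(members) == 1:
                singles += 1
                assert r.p_raw == uni[(members[0], r.contrast_name)]
        assert singles >= 1
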