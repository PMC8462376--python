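"""Statistical kernel against hand evaluations and independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mycogeo import (
    DistanceMatrix,
    benjamini_hochberg,
    bray_curtis,
    geographic_distance,
    mantel,
    permanova,
    t_test_two_sample,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# oracles


def bc_oracle(X):
    """Direct double-loop Bray-Curtis."""
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(X[i][k] - X[j][k]) for k in range(len(X[i])))
            den = sum(X[i][k] + X[j][k] for k in range(len(X[i])))
            D[i, j] = num / den if den else 0.0
    return D


def permanova_oracle(D, labels):
    """Exhaustive pseudo-F enumeration over all label orderings."""

    def F_of(lab):
        n = len(lab)
        groups = sorted(set(lab))
        d2 = D**2
        ss_tot = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g in groups:
            idx = [i for i, l in enumerate(lab) if l == g]
            ss_w += sum(d2[a, b] for a, b in itertools.combinations(idx, 2)) / len(idx)
        ss_b = ss_tot - ss_w
        return (ss_b / (len(groups) - 1)) / (ss_w / (n - len(groups)))

    F_obs = F_of(labels)
    count = total = 0
    for perm in itertools.permutations(labels):
        total += 1
        if F_of(list(perm)) >= F_obs - 1e-12:
            count += 1
    return F_obs, count / total


def mantel_oracle(D1, D2):
    """Exhaustive one-sided Mantel enumeration."""
    n = len(D1)
    iu = np.triu_indices(n, 1)

    def r_of(perm):
        return np.corrcoef(D1[iu], D2[np.ix_(perm, perm)][iu])[0, 1]

    r_obs = r_of(list(range(n)))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if r_of(list(perm)) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_identical_samples_give_zero(self):
        D = bray_curtis([[1, 2, 3], [1, 2, 3]]).values
        assert D[0, 1] == 0

    def test_disjoint_supports_give_one(self):
        D = bray_curtis([[5, 0], [0, 7]]).values
        assert D[0, 1] == 1

    def test_hand_evaluated_example(self):
        D = bray_curtis([[1, 2, 3], [3, 2, 1]]).values
        assert D[0, 1] == pytest.approx(4 / 12, abs=1e-15)

    def test_matches_double_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            X = rng.integers(0, 20, size=(rng.integers(2, 6), rng.integers(1, 5)))
            X[X.sum(axis=1) == 0, 0] = 1  # keep pairs defined
            assert np.abs(bray_curtis(X).values - bc_oracle(X.tolist())).max() < 1e-12

    def test_matches_skbio(self):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(7)
        X = rng.integers(1, 30, size=(6, 8)).astype(float)
        ours = bray_curtis(X).values
        theirs = skbio_diversity.beta_diversity("braycurtis", X).data
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_all_zero_pair_raises_naming_samples(self):
        with pytest.raises(ValueError, match="a.*c|all-zero"):
            bray_curtis([[0, 0], [1, 2], [0, 0]], labels=["a", "b", "c"])


class TestGeographicDistance:
    def test_three_four_five_triangle(self):
        D = geographic_distance([(0, 0), (3, 4)]).values
        assert D[0, 1] == pytest.approx(5.0)

    def test_identical_points_and_transect_diagonal(self):
        D = geographic_distance([(0, 0), (0, 0), (10, 40)]).values
        assert D[0, 1] == 0
        assert D[0, 2] == pytest.approx(math.sqrt(1700), rel=1e-12)


class TestPermanova:
    def _dist_aabb(self, eps=0.01):
        M = np.full((4, 4), 1.0)
        np.fill_diagonal(M, 0)
        M[0, 1] = M[1, 0] = M[2, 3] = M[3, 2] = eps
        return DistanceMatrix(("a", "b", "c", "d"), M)

    def test_exhaustive_aabb_gives_one_third(self):
        res = permanova(self._dist_aabb(), ["A", "A", "B", "B"], n_permutations=999, seed=0)
        assert res.exhaustive
        assert res.p_value == pytest.approx(8 / 24)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for n, labels in [(5, "AABBB"), (6, "AAABBB"), (6, "AABBCC")]:
            X = rng.uniform(1, 10, size=(n, 4))
            D = bray_curtis(X)
            res = permanova(D, list(labels), n_permutations=999, seed=1)
            F_or, p_or = permanova_oracle(D.values, list(labels))
            assert res.statistic == pytest.approx(F_or, rel=1e-10)
            assert res.p_value == pytest.approx(p_or, abs=0)

    def test_statistic_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        X = rng.uniform(0.5, 5, size=(12, 6))
        D = bray_curtis(X)
        labels = ["A"] * 6 + ["B"] * 6
        ours = permanova(D, labels, n_permutations=99, seed=0)
        dm = skbio_stats.DistanceMatrix(D.values, ids=list(D.labels))
        theirs = skbio_stats.permanova(dm, labels, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_all_zero_distances_flagged_degenerate(self):
        D = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        res = permanova(D, ["A", "A", "B", "B"])
        assert res.degenerate

    def test_r_squared_attached_and_bounded(self):
        res = permanova(self._dist_aabb(), ["A", "A", "B", "B"])
        assert 0 <= res.extras["R2"] <= 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(self._dist_aabb(), ["A", "A", "A", "A"])


class TestMantel:
    def _pair(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 2))
        d2 = geographic_distance(pts, labels=[str(i) for i in range(n)])
        noise = rng.uniform(0, 1, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d1 = DistanceMatrix(d2.labels, d2.values + noise)
        return d1, d2

    def test_identical_matrices_give_r_one_min_p(self):
        d1, d2 = self._pair(8, 0)
        res = mantel(d1, DistanceMatrix(d1.labels, d1.values.copy()), n_permutations=999, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 1 / 1000

    def test_affine_transform_gives_r_one(self):
        d1, _ = self._pair(7, 1)
        d2 = DistanceMatrix(d1.labels, 2.5 * d1.values)
        res = mantel(d1, d2, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_small_n(self):
        for n, seed in [(4, 2), (5, 3), (6, 4)]:
            d1, d2 = self._pair(n, seed)
            res = mantel(d1, d2, n_permutations=999, seed=0)
            r_or, p_or = mantel_oracle(d1.values, d2.values)
            assert res.exhaustive
            assert res.statistic == pytest.approx(r_or, rel=1e-10)
            assert res.p_value == pytest.approx(p_or, abs=0)

    def test_constant_matrix_flagged_degenerate(self):
        n = 5
        ones = np.ones((n, n)) - np.eye(n)
        d2, _ = self._pair(n, 5)
        d1 = DistanceMatrix(d2.labels, ones)
        assert mantel(d1, d2).degenerate


class TestWilcoxon:
    def test_exact_small_separated(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(2 / 6)

    def test_exact_full_separation_n20(self):
        res = wilcoxon_rank_sum(list(range(1, 11)), list(range(11, 21)))
        # n > 12: approximation path; check direction and smallness instead
        assert res.p_value < 1e-3

    def test_exact_enumeration_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.permutation(20)[:4] + rng.uniform(0, 0.4, 4)
            b = rng.permutation(30)[:5] + rng.uniform(0.5, 0.9, 5)
            ours = wilcoxon_rank_sum(a, b)
            theirs = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-12)

    def test_identical_samples_centered(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_normal_approximation_tracks_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        ours = wilcoxon_rank_sum(a, b)
        theirs = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-6)


class TestTTest:
    def test_identical_samples(self):
        res = t_test_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_pooled_hand_value(self):
        a, b = [0, 0, 1, 1], [1, 1, 2, 2]
        res = t_test_two_sample(a, b, variant="pooled")
        # sp2 = 1/3, se = sqrt(1/3 * 1/2), t = -1 / sqrt(1/6)
        assert abs(res.statistic) == pytest.approx(math.sqrt(6), rel=1e-12)
        theirs = sps.ttest_ind(a, b)
        assert res.p_value == pytest.approx(theirs.pvalue, rel=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.3, 2, 35)
        res = t_test_two_sample(a, b)
        theirs = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(theirs.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(theirs.pvalue, rel=1e-12)

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1, 50)
            if t_test_two_sample(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_zero_variance_both_flagged(self):
        res = t_test_two_sample([1, 1], [1, 1])
        assert res.degenerate


class TestBenjaminiHochberg:
    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_one(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(benjamini_hochberg([1, 1, 1]), [1, 1, 1])

    def test_never_decreases_and_idempotent(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 25)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        np.testing.assert_allclose(benjamini_hochberg(adj), benjamini_hochberg(adj))

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 40)
        _, theirs, *_ = sm.multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), theirs, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])
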