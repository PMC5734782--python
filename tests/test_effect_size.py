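"""ANOSIM / PERMANOVA statistics against hand values, enumeration, and oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from betaci import (
    DegenerateInputError,
    DistanceMatrix,
    GroupMap,
    InputError,
    anosim_r,
    permanova,
    permutation_test,
)
from betaci.effect_size import (
    anosim_from_condensed,
    permanova_from_condensed,
)


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float).reshape(len(points), -1)
    ids = tuple(ids or (f"s{i}" for i in range(len(points))))
    return DistanceMatrix(ids, squareform(pdist(points)))


def distinct_assignments(labels):
    """All distinct label vectors obtainable by permuting ``labels``."""
    return sorted(set(itertools.permutations(labels)))


class TestAnosimR:
    def test_perfect_separation_gives_one(self):
        d = euclidean_dm([0.0, 0.1, 10.0, 10.1])
        groups = GroupMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert anosim_r(d, groups) == pytest.approx(1.0, abs=1e-12)

    def test_hand_ranked_two_plus_two_is_zero(self):
        # within {0.1, 0.6}, between {0.2, 0.3, 0.4, 0.5}: both mean ranks 3.5
        values = np.zeros((4, 4))
        pairs = {(0, 1): 0.1, (2, 3): 0.6, (0, 2): 0.2, (0, 3): 0.3,
                 (1, 2): 0.4, (1, 3): 0.5}
        for (i, j), v in pairs.items():
            values[i, j] = values[j, i] = v
        d = DistanceMatrix(("a1", "a2", "b1", "b2"), values)
        groups = GroupMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert anosim_r(d, groups) == pytest.approx(0.0, abs=1e-12)

    def test_mean_over_exhaustive_label_permutations_is_zero(self):
        rng = np.random.default_rng(42)
        d = pdist(rng.random((7, 3)))
        labels = np.array([0, 0, 0, 1, 1, 2, 2])
        stats = [anosim_from_condensed(d, np.array(p))
                 for p in distinct_assignments(labels)]
        assert np.mean(stats) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_samples_tie_handling(self):
        # bootstrap-style duplicates: zero distances within groups, no error
        points = [0.0, 0.0, 1.0, 1.0, 1.5]
        d = euclidean_dm(points)
        groups = GroupMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "B"})
        r = anosim_r(d, groups)
        assert -1.0 <= r <= 1.0


class TestPermanova:
    def test_two_point_groups_hand_case(self):
        # {0,0} vs {1,1}: SS_T = 1, SS_W = 0 -> R² = 1, pseudo-F sentinel +inf
        d = euclidean_dm([0.0, 0.0, 1.0, 1.0])
        groups = GroupMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        pseudo_f, r2 = permanova(d, groups)
        assert r2 == 1.0
        assert np.isinf(pseudo_f)

    def test_partition_identity_and_range(self):
        rng = np.random.default_rng(7)
        d = pdist(rng.random((8, 4)))
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        pseudo_f, r2 = permanova_from_condensed(d, labels)
        assert 0.0 <= r2 <= 1.0
        assert pseudo_f >= 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_univariate_pseudo_f_equals_anova_f(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 8, size=int(rng.integers(2, 4)))
        samples = [rng.normal(g, 1.0, size=n) for g, n in enumerate(sizes)]
        y = np.concatenate(samples)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        d = pdist(y.reshape(-1, 1))
        pseudo_f, _ = permanova_from_condensed(d, labels)
        assert pseudo_f == pytest.approx(f_oneway(*samples).statistic, abs=1e-8)

    def test_mean_r2_over_exhaustive_permutations(self):
        # E[R²] over the exact permutation distribution = (a-1)/(N-1)
        rng = np.random.default_rng(3)
        for labels in ([0, 0, 0, 1, 1, 1], [0, 0, 1, 1, 2, 2], [0, 0, 0, 1, 1, 2, 2]):
            labels = np.array(labels)
            d = pdist(rng.random((labels.size, 3)))
            r2s = [permanova_from_condensed(d, np.array(p))[1]
                   for p in distinct_assignments(labels)]
            a, n = np.unique(labels).size, labels.size
            assert np.mean(r2s) == pytest.approx((a - 1) / (n - 1), abs=1e-12)

    def test_all_identical_samples_degenerate(self):
        d = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        groups = GroupMap({"a": "A", "b": "A", "c": "B", "d": "B"})
        with pytest.raises(DegenerateInputError):
            permanova(d, groups)


class TestPermutationTest:
    def _separated_3_plus_3(self):
        d = euclidean_dm([0.0, 0.05, 0.1, 5.0, 5.05, 5.1])
        groups = GroupMap({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
        return d, groups

    def test_exhaustive_p_for_separated_design_is_one_tenth(self):
        # 10 distinct 3+3 splits; only the observed one reaches R = 1
        d, groups = self._separated_3_plus_3()
        labels = np.array([0, 0, 0, 1, 1, 1])
        cond = d.condensed()
        observed = anosim_from_condensed(cond, labels)
        stats = [anosim_from_condensed(cond, np.array(p))
                 for p in distinct_assignments(labels)]
        exact_p = np.mean([s >= observed - 1e-12 for s in stats])
        assert exact_p == pytest.approx(0.1, abs=1e-15)

    def test_monte_carlo_p_within_binomial_error_of_exact(self):
        d, groups = self._separated_3_plus_3()
        result = permutation_test(d, groups, "ANOSIM", n_permutations=10_000, seed=5)
        exact = 0.1
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(result.p_value - exact) < 3 * se
        assert result.statistic == pytest.approx(1.0, abs=1e-12)

    def test_statistic_is_seed_free_and_p_bounds_hold(self):
        d, groups = self._separated_3_plus_3()
        r1 = permutation_test(d, groups, "ANOSIM", n_permutations=99, seed=1)
        r2 = permutation_test(d, groups, "ANOSIM", n_permutations=99, seed=2)
        assert r1.statistic == r2.statistic
        single = permutation_test(d, groups, "ANOSIM", n_permutations=1, seed=3)
        assert single.p_value in (0.5, 1.0)

    def test_permanova_p_matches_anosim_direction(self):
        d, groups = self._separated_3_plus_3()
        result = permutation_test(d, groups, "PERMANOVA", n_permutations=999, seed=0)
        assert result.p_value < 0.2
        assert result.pseudo_F > 0
        assert 0 <= result.statistic <= 1


class TestValidationAndInvariance:
    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        points = rng.random((8, 3))
        ids = [f"s{i}" for i in range(8)]
        groups = GroupMap({s: ("A" if i < 4 else "B") for i, s in enumerate(ids)})
        d = euclidean_dm(points, ids)
        perm = rng.permutation(8)
        d_perm = DistanceMatrix(
            tuple(ids[i] for i in perm), d.values[np.ix_(perm, perm)]
        )
        assert anosim_r(d, groups) == pytest.approx(anosim_r(d_perm, groups), abs=1e-12)
        assert permanova(d, groups)[1] == pytest.approx(
            permanova(d_perm, groups)[1], abs=1e-12
        )

    def test_group_of_one_rejected(self):
        d = euclidean_dm([0.0, 1.0, 2.0])
        groups = GroupMap({"s0": "A", "s1": "A", "s2": "B"})
        with pytest.raises(InputError, match="fewer than 2"):
            anosim_r(d, groups)

    def test_sample_missing_from_group_map_rejected(self):
        d = euclidean_dm([0.0, 1.0, 2.0, 3.0])
        groups = GroupMap({"s0": "A", "s1": "A", "s2": "B"})
        with pytest.raises(InputError, match="absent from the group map"):
            anosim_r(d, groups)


class TestReferenceCrossCheck:
    """scikit-bio as independent oracle for both statistics (tests only)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_statistics_match_skbio(self, seed):
        import skbio
        from skbio.stats.distance import anosim as sk_anosim
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(seed)
        points = rng.random((10, 4))
        ids = [f"s{i}" for i in range(10)]
        grouping = ["A"] * 5 + ["B"] * 5
        dm = euclidean_dm(points, ids)
        sk_dm = skbio.DistanceMatrix(dm.values.copy(), ids=ids)
        groups = GroupMap(dict(zip(ids, grouping)))

        ours = anosim_r(dm, groups)
        theirs = sk_anosim(sk_dm, grouping, permutations=0)["test statistic"]
        assert ours == pytest.approx(theirs, abs=1e-12)

        ours_f, _ = permanova(dm, groups)
        theirs_f = sk_permanova(sk_dm, grouping, permutations=0)["test statistic"]
        assert ours_f == pytest.approx(theirs_f, abs=1e-10)
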