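"""Distance-based permutation statistics, with brute-force oracles.

The oracles below re-derive each statistic from its definition (direct sums,
explicit rank enumeration, exhaustive labelings) independently of the
implementation; scikit-bio provides an extra cross-check of the PERMANOVA
and ANOSIM statistics on random data.
"""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from ffpm import (
    DistanceMatrix,
    PermutationSettings,
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    global_scan,
    mrpp,
    permanova,
    upgma_dendrogram,
)

EXACT = PermutationSettings(n_perm=1, exact_enumeration=True)


def euclidean_dm(points, labels=None):
    points = np.asarray(points, dtype=float).reshape(len(points), -1)
    values = squareform(pdist(points))
    labels = labels or tuple(f"s{i}" for i in range(len(points)))
    return DistanceMatrix(labels=tuple(labels), values=values)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_permanova_F(d, codes):
    """Pseudo-F from explicit pair sums."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    groups = sorted(set(codes))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, c in enumerate(codes) if c == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    if ss_within == 0:
        return np.inf, ss_total, ss_between
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_total, ss_between


def oracle_anosim_R(d, codes):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [codes[i] == codes[j] for i, j in pairs]
    rw = np.mean([r for r, w in zip(ranks, within) if w])
    rb = np.mean([r for r, w in zip(ranks, within) if not w])
    return (rb - rw) / (len(pairs) / 2)


def oracle_mrpp_delta(d, codes):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    delta = 0.0
    for g in sorted(set(codes)):
        idx = [i for i, c in enumerate(codes) if c == g]
        within = [d[i, j] for i in idx for j in idx if i < j]
        delta += (len(idx) / n) * np.mean(within)
    return delta


def all_labelings(codes):
    seen = set()
    for perm in itertools.permutations(codes):
        if perm not in seen:
            seen.add(perm)
            yield list(perm)


def oracle_exact_p(d, codes, stat, extreme="ge"):
    obs = stat(d, codes)
    null = [stat(d, lab) for lab in all_labelings(codes)]
    if extreme == "ge":
        count = sum(s >= obs for s in null)
    else:
        count = sum(s <= obs for s in null)
    return count / len(null)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 0], [0, 1], 1.0),
            ([2, 1], [1, 1], 0.2),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_negative_entries_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="ffpm"):
            value = bray_curtis([1.0, -0.2], [1.0, 0.0])
        assert value == pytest.approx(0.0)
        assert "clamped" in caplog.text

    def test_both_all_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0.0, 0.0], [0.0, -0.1])

    def test_matrix_is_valid_distance_object(self):
        import pandas as pd

        table = pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0], [5.0, 5.0]], index=["a", "b", "c"]
        )
        dm = bray_curtis_matrix(table)
        assert dm.labels == ("a", "b", "c")
        assert dm.values[0, 1] == pytest.approx(2 / 6)
        assert (dm.values >= 0).all()
        assert np.allclose(dm.values, dm.values.T)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class TestPermanova:
    def test_four_point_line_instance(self):
        dm = euclidean_dm([[0.0], [1.0], [3.0], [4.0]])
        groups = ["a", "a", "b", "b"]
        f_oracle, ss_total, ss_between = oracle_permanova_F(dm.values, groups)
        assert ss_total == pytest.approx(10.0)
        assert ss_between == pytest.approx(9.0)
        res = permanova(dm, groups, EXACT)
        assert res.F == pytest.approx(18.0) == pytest.approx(f_oracle)
        assert res.r2 == pytest.approx(0.9)
        # the mirror labeling attains the same F, so 2 of the 6 balanced
        # labelings reach the observed statistic
        assert res.p == pytest.approx(
            oracle_exact_p(dm.values, groups, lambda d, c: oracle_permanova_F(d, c)[0])
        )
        assert res.p == pytest.approx(2 / 6)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        order = rng.permutation(8)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        r1 = permanova(euclidean_dm(pts), list(groups), EXACT)
        r2 = permanova(euclidean_dm(pts[order]), list(groups[order]), EXACT)
        assert r1.F == pytest.approx(r2.F)
        assert r1.r2 == pytest.approx(r2.r2)
        assert r1.p == pytest.approx(r2.p)

    def test_partition_of_sums_of_squares(self):
        rng = np.random.default_rng(1)
        d2 = euclidean_dm(rng.normal(size=(10, 4))).values ** 2
        from ffpm.community_stats import _encode_groups, _permanova_stats

        codes = _encode_groups(["a"] * 5 + ["b"] * 5)
        n = 10
        ss_total = d2.sum() / (2 * n)
        ss_within = sum(
            d2[np.ix_(np.flatnonzero(codes == g), np.flatnonzero(codes == g))].sum()
            / (2 * 5)
            for g in (0, 1)
        )
        f, r2 = _permanova_stats(d2, codes, 2)
        assert r2 == pytest.approx((ss_total - ss_within) / ss_total, rel=1e-10)

    def test_singleton_group_rejected(self):
        dm = euclidean_dm([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="at least 2 samples"):
            permanova(dm, ["a", "b", "b"], EXACT)

    def test_statistic_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(10, 6))
        dm = euclidean_dm(pts)
        groups = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, groups, PermutationSettings(n_perm=99, seed=0))
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values, list(dm.labels)),
            groups,
            permutations=0,
        )
        assert ours.F == pytest.approx(float(sk["test statistic"]), rel=1e-9)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

class TestAnosim:
    def test_complete_separation_gives_R_one(self):
        pts = [[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]]
        dm = euclidean_dm(pts)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = anosim(dm, groups, EXACT)
        assert res.R == pytest.approx(1.0)
        assert res.p == pytest.approx(
            oracle_exact_p(dm.values, groups, oracle_anosim_R)
        )

    def test_four_point_instance_matches_rank_oracle(self):
        dm = euclidean_dm([[0.0], [1.0], [3.0], [7.0]])
        groups = ["a", "a", "b", "b"]
        res = anosim(dm, groups, EXACT)
        assert res.R == pytest.approx(oracle_anosim_R(dm.values, groups))
        assert res.p == pytest.approx(
            oracle_exact_p(dm.values, groups, oracle_anosim_R)
        )

    def test_null_R_small_on_average(self):
        rng = np.random.default_rng(7)
        values = []
        for _ in range(30):
            dm = euclidean_dm(rng.normal(size=(10, 5)))
            res = anosim(
                dm, ["a"] * 5 + ["b"] * 5, PermutationSettings(n_perm=1, seed=0)
            )
            values.append(res.R)
        assert abs(np.mean(values)) < 0.1

    def test_statistic_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        dm = euclidean_dm(rng.normal(size=(9, 4)))
        groups = ["a"] * 4 + ["b"] * 5
        ours = anosim(dm, groups, PermutationSettings(n_perm=9, seed=0))
        sk = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(dm.values, list(dm.labels)),
            groups,
            permutations=0,
        )
        assert ours.R == pytest.approx(float(sk["test statistic"]), rel=1e-9)


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------

class TestMrpp:
    def test_all_equal_distances_give_zero_A(self):
        n = 6
        values = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(labels=tuple(f"s{i}" for i in range(n)), values=values)
        res = mrpp(dm, ["a"] * 3 + ["b"] * 3, EXACT)
        assert res.A == pytest.approx(0.0, abs=1e-12)

    def test_separated_clusters_positive_A_minimum_p(self):
        pts = [[0.0], [0.05], [0.1], [5.0], [5.05], [5.1]]
        dm = euclidean_dm(pts)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = mrpp(dm, groups, EXACT)
        assert res.A > 0
        n_labelings = 20  # C(6,3)
        assert res.p == pytest.approx(
            oracle_exact_p(dm.values, groups, oracle_mrpp_delta, extreme="le")
        )
        assert res.p <= 2 / n_labelings  # observed and its mirror

    def test_four_point_instance_matches_enumeration_oracle(self):
        dm = euclidean_dm([[0.0], [1.5], [3.0], [7.0]])
        groups = ["a", "a", "b", "b"]
        res = mrpp(dm, groups, EXACT)
        assert res.delta == pytest.approx(oracle_mrpp_delta(dm.values, groups))
        assert res.p == pytest.approx(
            oracle_exact_p(dm.values, groups, oracle_mrpp_delta, extreme="le")
        )
        deltas = [
            oracle_mrpp_delta(dm.values, lab) for lab in all_labelings(groups)
        ]
        assert res.expected_delta == pytest.approx(np.mean(deltas))
        assert res.A == pytest.approx(1 - res.delta / np.mean(deltas))

    def test_alternative_weightings_accepted(self):
        dm = euclidean_dm([[0.0], [1.0], [3.0], [7.0], [8.0], [9.0]])
        groups = ["a", "a", "a", "b", "b", "b"]
        for weighting in ("fraction", "dof", "pairs"):
            res = mrpp(dm, groups, EXACT, weighting=weighting)
            assert np.isfinite(res.A)
        with pytest.raises(ValueError, match="weighting"):
            mrpp(dm, groups, EXACT, weighting="bogus")


# ---------------------------------------------------------------------------
# exact enumeration == brute force for all three tests
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_per_group", [2, 3, 4])
def test_exact_enumeration_matches_brute_force(n_per_group):
    rng = np.random.default_rng(100 + n_per_group)
    pts = rng.normal(size=(2 * n_per_group, 3))
    dm = euclidean_dm(pts)
    groups = ["a"] * n_per_group + ["b"] * n_per_group
    assert permanova(dm, groups, EXACT).p == pytest.approx(
        oracle_exact_p(dm.values, groups, lambda d, c: oracle_permanova_F(d, c)[0])
    )
    assert anosim(dm, groups, EXACT).p == pytest.approx(
        oracle_exact_p(dm.values, groups, oracle_anosim_R)
    )
    assert mrpp(dm, groups, EXACT).p == pytest.approx(
        oracle_exact_p(dm.values, groups, oracle_mrpp_delta, extreme="le")
    )


def test_monte_carlo_p_respects_floor_and_seeding():
    rng = np.random.default_rng(5)
    dm = euclidean_dm(np.vstack([rng.normal(size=(5, 3)), 10 + rng.normal(size=(5, 3))]))
    groups = ["a"] * 5 + ["b"] * 5
    settings = PermutationSettings(n_perm=99, seed=12)
    res1 = permanova(dm, groups, settings)
    res2 = permanova(dm, groups, settings)
    assert res1 == res2  # identical permutation stream
    assert res1.p >= 1 / 100


# ---------------------------------------------------------------------------
# UPGMA dendrograms
# ---------------------------------------------------------------------------

class TestUpgma:
    def test_two_leaves_split_the_distance(self):
        dm = DistanceMatrix(labels=("A", "B"), values=np.array([[0, 0.4], [0.4, 0]]))
        assert upgma_dendrogram(dm) == "(A:0.2,B:0.2);"

    def test_closest_pair_merges_first_at_average_height(self):
        values = np.array(
            [
                [0.0, 1.0, 4.0],
                [1.0, 0.0, 4.0],
                [4.0, 4.0, 0.0],
            ]
        )
        dm = DistanceMatrix(labels=("A", "B", "C"), values=values)
        newick = upgma_dendrogram(dm)
        # A,B at height 0.5; C joins at height 2 -> inner branch 1.5
        assert newick == "((A:0.5,B:0.5):1.5,C:2);"

    def test_label_permutation_preserves_topology(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        dm = euclidean_dm(pts, labels=[f"L{i}" for i in range(6)])
        order = [3, 1, 5, 0, 2, 4]
        dm_perm = euclidean_dm(pts[order], labels=[f"L{i}" for i in order])

        def leafsets(newick):
            from io import StringIO

            from skbio import TreeNode

            tree = TreeNode.read(StringIO(newick))
            return {
                frozenset(tip.name for tip in node.tips())
                for node in tree.non_tips(include_self=True)
            }

        assert leafsets(upgma_dendrogram(dm)) == leafsets(upgma_dendrogram(dm_perm))

    def test_unsupported_linkage_rejected(self):
        dm = DistanceMatrix(labels=("A", "B"), values=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="linkage"):
            upgma_dendrogram(dm, linkage="ward")


# ---------------------------------------------------------------------------
# global scan
# ---------------------------------------------------------------------------

class TestGlobalScan:
    def test_full_grid_gives_14_rows(self, layout, sim_default):
        dataset, _ = sim_default
        results = global_scan(
            dataset, layout, PermutationSettings(n_perm=99, seed=1)
        )
        assert len(results) == 14
        assert [r.time for r in results] == [0.5 * k for k in range(1, 15)]

    def test_planted_effect_grows_from_lag_to_stationary(self, layout, sim_default):
        dataset, _ = sim_default
        results = global_scan(
            dataset, layout, PermutationSettings(n_perm=99, seed=1)
        )
        assert results[-1].permanova_R2 > results[0].permanova_R2
        assert results[-1].permanova_p <= 0.05

    def test_scan_is_deterministic_given_seed(self, layout, sim_default):
        dataset, _ = sim_default
        settings = PermutationSettings(n_perm=49, seed=5)
        r1 = global_scan(dataset, layout, settings)
        r2 = global_scan(dataset, layout, settings)
        assert r1 == r2
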