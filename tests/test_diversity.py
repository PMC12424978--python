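"""Beta-diversity metrics, NJ tree, PCoA, and PERMANOVA, validated against
brute-force oracles and independent scikit-bio implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from oracles import enumerate_unifrac, random_tree

from longamp import (
    FeatureTable,
    beta_diversity,
    bray_curtis,
    build_tree,
    canonical_newick,
    jaccard,
    pcoa,
    permanova,
    unifrac,
)


class TestBrayCurtisJaccard:
    def test_identity_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0
        assert bray_curtis([5, 0], [0, 3]) == 1
        assert jaccard([1, 1, 0], [1, 1, 0]) == 0
        assert jaccard([1, 0], [0, 1]) == 1

    def test_worked_examples(self):
        assert bray_curtis([6, 0, 2], [0, 4, 2]) == pytest.approx(10 / 14)
        # supports {A,C} vs {B,C}
        assert jaccard([1, 0, 1], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            jaccard([0], [0])

    def test_agrees_with_scipy(self, rng):
        from scipy.spatial.distance import braycurtis as sp_bc
        from scipy.spatial.distance import jaccard as sp_j
        for _ in range(50):
            x = rng.integers(0, 20, size=8)
            y = rng.integers(0, 20, size=8)
            if x.sum() == 0 and y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(sp_bc(x, y))
            assert jaccard(x, y) == pytest.approx(sp_j(x > 0, y > 0))


class TestUnifrac:
    def test_self_distance_zero(self, rng):
        tree = random_tree(rng, 5)
        x = {f"L{i}": int(c) for i, c in enumerate(rng.integers(1, 10, 5))}
        assert unifrac(tree, x, dict(x), weighted=False) == 0
        assert unifrac(tree, x, dict(x), weighted=True) == 0

    def test_two_leaf_disjoint_is_one(self):
        from skbio import TreeNode
        tree = TreeNode.read(["(L1:1,L2:1);"])
        assert unifrac(tree, {"L1": 1}, {"L2": 1}, weighted=False) == 1

    @pytest.mark.parametrize("weighted", [False, True])
    def test_agrees_with_branch_enumeration_oracle(self, weighted):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            tree = random_tree(rng, n)
            x = {f"L{i}": int(v) for i, v in enumerate(rng.integers(0, 6, n))}
            y = {f"L{i}": int(v) for i, v in enumerate(rng.integers(0, 6, n))}
            if sum(x.values()) == 0 or sum(y.values()) == 0:
                continue
            mine = unifrac(tree, x, y, weighted=weighted)
            ref = enumerate_unifrac(tree, x, y, weighted=weighted)
            assert mine == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_agrees_with_skbio(self, weighted):
        from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            tree = random_tree(rng, n)
            taxa = [f"L{i}" for i in range(n)]
            u = rng.integers(0, 6, n)
            v = rng.integers(0, 6, n)
            if u.sum() == 0 or v.sum() == 0:
                continue
            mine = unifrac(tree, dict(zip(taxa, u)), dict(zip(taxa, v)),
                           weighted=weighted)
            fn = weighted_unifrac if weighted else unweighted_unifrac
            ref = fn(u, v, taxa=taxa, tree=tree)
            assert mine == pytest.approx(float(ref), abs=1e-10)

    def test_missing_feature_named_in_error(self, rng):
        tree = random_tree(rng, 3)
        with pytest.raises(ValueError, match="GHOST"):
            unifrac(tree, {"L0": 1, "GHOST": 2}, {"L1": 1})


class TestBuildTree:
    def test_two_sequences_cherry(self):
        tree = build_tree({"a": "AAAA", "b": "AATT"})
        tips = {t.name: t.length for t in tree.tips()}
        assert set(tips) == {"a", "b"}
        assert sum(tips.values()) == pytest.approx(0.5)  # p-distance 2/4

    def test_additive_distances_recover_topology(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=200))

        def mutate(s, positions):
            s = list(s)
            for p in positions:
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s)

        seqs = {
            "a": base,
            "b": mutate(base, range(0, 4)),        # d(a,b)=4
            "c": mutate(base, range(100, 140)),    # far clade
            "d": mutate(base, list(range(100, 140)) + list(range(4, 10))),
        }
        tree = build_tree(seqs)
        nwk = canonical_newick(tree)
        # a-b and c-d must form cherries
        parents = {t.name: t.parent for t in tree.tips()}
        assert parents["a"] is parents["b"] or parents["c"] is parents["d"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(23)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(6)}
        t1 = canonical_newick(build_tree(dict(seqs)))
        shuffled = dict(reversed(list(seqs.items())))
        t2 = canonical_newick(build_tree(shuffled))
        assert t1 == t2

    def test_all_branch_lengths_non_negative(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(8)}
        tree = build_tree(seqs)
        assert all((n.length or 0) >= 0 for n in tree.traverse())

    def test_duplicate_or_single_rejected(self):
        with pytest.raises(ValueError):
            build_tree({"a": "ACGT"})


class TestPcoa:
    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(d)
        assert (res.eigenvalues[:3] > 1e-8).all()
        assert np.all(np.abs(res.eigenvalues[3:]) < 1e-8)
        coords = res.coordinates.to_numpy()[:, :3]
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-8)

    def test_equilateral_triplet_has_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_two_samples(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = pcoa(d)
        assert res.coordinates.shape[1] == 1
        assert sorted(res.coordinates["PC1"].tolist()) == pytest.approx([-1.0, 1.0])

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]], dtype=float))

    def test_matches_skbio_on_jaccard_matrix(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa
        counts = pd.DataFrame(rng.integers(0, 3, size=(12, 6)),
                              index=[f"f{i}" for i in range(12)],
                              columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] += 1
        table = FeatureTable(counts, {f"f{i}": "ACGT" for i in range(12)})
        dm = beta_diversity(table, "jaccard")
        mine = pcoa(dm)
        ref = skbio_pcoa(DistanceMatrix(dm.data, ids=dm.ids))
        k = mine.coordinates.shape[1]
        assert np.allclose(np.sort(mine.eigenvalues[:k]),
                           np.sort(ref.eigvals.to_numpy()[:k]), atol=1e-8)


def block_distance_matrix(n_per_group=3, within=1.0, between=2.0):
    n = 2 * n_per_group
    d = np.full((n, n), between)
    d[:n_per_group, :n_per_group] = within
    d[n_per_group:, n_per_group:] = within
    np.fill_diagonal(d, 0.0)
    return d


class TestPermanova:
    def test_exhaustive_toy_p(self):
        """Two groups of 3, within 1, between 2: 2 of the 20 balanced
        assignments reach the observed F, so p = 0.1 exactly."""
        d = block_distance_matrix()
        res = permanova(d, ["a"] * 3 + ["b"] * 3)
        assert res.method == "exhaustive"
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(0.1)

    def test_degenerate_zero_distances(self):
        res = permanova(np.zeros((4, 4)), ["a", "a", "b", "b"])
        assert res.r_squared == 0.0
        assert res.p_value == 1.0

    def test_zero_within_group_ss_gives_inf_f(self):
        d = block_distance_matrix(within=0.0, between=1.0)
        res = permanova(d, ["a"] * 3 + ["b"] * 3, exhaustive=True)
        assert np.isinf(res.pseudo_F)
        assert res.p_value <= 0.1

    def test_r2_invariant_to_relabeling_and_order(self, rng):
        n = 9
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        groups = ["x"] * 4 + ["y"] * 5
        r1 = permanova(d, groups, 99, seed=1)
        r2 = permanova(d, ["y" if g == "x" else "x" for g in groups], 99, seed=1)
        assert r1.r_squared == pytest.approx(r2.r_squared)
        perm = rng.permutation(n)
        r3 = permanova(d[np.ix_(perm, perm)], [groups[i] for i in perm], 99, seed=1)
        assert r1.r_squared == pytest.approx(r3.r_squared)

    def test_seed_reproducibility(self, rng):
        m = rng.random((12, 12))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        groups = ["a"] * 6 + ["b"] * 6
        r1 = permanova(d, groups, 999, seed=7, exhaustive=False)
        r2 = permanova(d, groups, 999, seed=7, exhaustive=False)
        assert r1.p_value == r2.p_value

    def test_matches_skbio_statistic(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        m = rng.random((10, 10))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        groups = ["a"] * 4 + ["b"] * 6
        mine = permanova(d, groups, 99, seed=0, exhaustive=False)
        ref = skbio_permanova(DistanceMatrix(d), grouping=groups, permutations=99)
        assert mine.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.zeros((3, 3)), ["a", "a", "a"])


class TestBetaDiversityWrapper:
    def test_metric_symmetry_and_range(self, small_community, designs):
        from longamp import dereplicate_asvs, generate_community, generate_reads
        taxa = sorted(small_community)
        truth = generate_community(taxa, n_per_cohort=3,
                                   effects={taxa[0]: 2.0}, seed=41)
        rs = generate_reads(truth, small_community, designs["STRAINID"],
                            depth=400, seed=42)
        table = dereplicate_asvs(rs.reads)
        tree = build_tree(table.sequences)
        for metric in ("braycurtis", "jaccard", "unweighted_unifrac",
                       "weighted_unifrac"):
            dm = beta_diversity(table, metric, tree)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)
            assert (dm.data >= 0).all()
            if metric != "weighted_unifrac":
                assert (dm.data <= 1 + 1e-12).all()
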