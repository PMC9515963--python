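"""Alpha/beta diversity against hand computations, brute-force oracles and
scikit-bio cross-checks."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity import alpha_diversity as skbio_alpha, beta_diversity as skbio_beta
from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

from stomabiome import diversity
from stomabiome.bundle_io import FeatureTable, PhyloTree


def random_tree(tip_names, seed):
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t) for t in tip_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])


def make_table(rows, features, **kw):
    return FeatureTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(len(rows))], columns=features), **kw)


class TestAlpha:
    def test_uniform_eight_features_is_three_bits(self):
        t = make_table([[1] * 8], [f"f{i}" for i in range(8)])
        out = diversity.alpha_diversity(t.relabund(), "shannon")
        assert out["value"].iloc[0] == pytest.approx(3.0)

    def test_single_feature_zero_entropy(self):
        t = make_table([[0, 7, 0]], list("abc"))
        sh = diversity.alpha_diversity(t, "shannon")["value"].iloc[0]
        obs = diversity.alpha_diversity(t, "observed")["value"].iloc[0]
        assert sh == pytest.approx(0.0)
        assert obs == 1

    def test_uniform_maximizes_shannon(self):
        rng = np.random.default_rng(1)
        uniform = np.full(10, 0.1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(10))
            t = make_table([uniform, p], [f"f{i}" for i in range(10)],
                           kind="relabund")
            out = diversity.alpha_diversity(t, "shannon")["value"]
            assert out.iloc[0] >= out.iloc[1] - 1e-12

    def test_feature_order_invariance(self):
        t1 = make_table([[3, 1, 6]], list("abc"))
        t2 = make_table([[6, 3, 1]], list("cab"))
        s1 = diversity.alpha_diversity(t1, "shannon")["value"].iloc[0]
        s2 = diversity.alpha_diversity(t2, "shannon")["value"].iloc[0]
        assert s1 == pytest.approx(s2)

    def test_zero_total_sample_rejected(self):
        t = make_table([[0, 0]], list("ab"))
        with pytest.raises(ValueError):
            diversity.alpha_diversity(t, "shannon")


class TestFaithsPD:
    def test_hand_computed_path_unions(self):
        tree = PhyloTree(TreeNode.read(["((A:1,B:1):1,C:2):0;"]))
        assert diversity.faiths_pd(["A"], tree) == pytest.approx(2.0)
        assert diversity.faiths_pd(["A", "B", "C"], tree) == pytest.approx(5.0)

    def test_monotone_and_total_length(self):
        tree = random_tree([f"t{i}" for i in range(12)], seed=4)
        tips = tree.tip_names
        pd_prev = 0.0
        for k in range(1, len(tips) + 1):
            pd_k = diversity.faiths_pd(tips[:k], tree)
            assert pd_k >= pd_prev - 1e-12
            pd_prev = pd_k
        assert pd_prev == pytest.approx(tree.total_length())

    def test_matches_skbio(self):
        tree = random_tree(list("ABCDEF"), seed=7)
        counts = np.array([[1, 0, 3, 0, 2, 0], [0, 1, 1, 1, 0, 1]])
        ours = [diversity.faiths_pd(np.array(list("ABCDEF"))[row > 0], tree)
                for row in counts]
        ref = skbio_alpha("faith_pd", counts, ids=["x", "y"],
                          taxa=list("ABCDEF"), tree=tree.tree)
        assert np.allclose(ours, ref.to_numpy())

    def test_requires_tree_and_asv_level(self, tiny_bundle):
        with pytest.raises(ValueError):
            diversity.alpha_diversity(tiny_bundle.table, "faiths_pd")
        with pytest.raises(ValueError):
            diversity.alpha_diversity(tiny_bundle.table, "faiths_pd",
                                      tree=tiny_bundle.tree, level="KO")


def unifrac_oracle(tree: PhyloTree, rel: FeatureTable, i, j, weighted):
    """Naive per-branch summation, independent of the implementation's
    incidence-matrix path."""
    feats = rel.feature_ids
    vi = dict(zip(feats, rel.values[i]))
    vj = dict(zip(feats, rel.values[j]))
    num = den = 0.0
    for node in tree.tree.postorder():
        if node.is_root():
            continue
        tips = {t.name for t in node.tips()} or {node.name}
        pi = sum(vi.get(t, 0.0) for t in tips)
        pj = sum(vj.get(t, 0.0) for t in tips)
        if weighted:
            num += node.length * abs(pi - pj)
        else:
            if pi > 0 or pj > 0:
                den += node.length
                if (pi > 0) != (pj > 0):
                    num += node.length
    return num if weighted else (num / den if den else 0.0)


class TestUniFrac:
    def test_identical_samples_distance_zero(self):
        tree = random_tree(list("ABCD"), seed=0)
        t = make_table([[1, 2, 3, 4], [1, 2, 3, 4]], list("ABCD"))
        for weighted in (False, True):
            dm = diversity.unifrac(t, tree, weighted=weighted)
            assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_on_star_tree(self):
        star = TreeNode.read(["(A:1,B:1,C:1,D:1):0;"])
        tree = PhyloTree(star)
        t = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], list("ABCD"))
        dm = diversity.unifrac(t, tree, weighted=False)
        assert dm.data[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("weighted", [False, True])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_branch_by_branch_oracle(self, weighted, seed):
        tree = random_tree(list("ABCDE"), seed=seed)
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(4, 5))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = make_table(counts.tolist(), list("ABCDE")).relabund()
        dm = diversity.unifrac(t, tree, weighted=weighted)
        for i in range(4):
            for j in range(i + 1, 4):
                assert dm.data[i, j] == pytest.approx(
                    unifrac_oracle(tree, t, i, j, weighted), abs=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_skbio_on_integer_counts(self, weighted):
        tree = random_tree(list("ABCDEF"), seed=11)
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, size=(5, 6))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = make_table(counts.tolist(), list("ABCDEF"))
        ours = diversity.unifrac(t, tree, weighted=weighted)
        metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
        ref = skbio_beta(metric, counts, ids=t.sample_ids,
                         taxa=t.feature_ids, tree=tree.tree)
        assert np.allclose(ours.data, ref.data, atol=1e-10)

    def test_triangle_inequality_unweighted(self):
        tree = random_tree([f"t{i}" for i in range(8)], seed=5)
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=(6, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dm = diversity.unifrac(make_table(counts.tolist(), tree.tip_names),
                               tree, weighted=False)
        d = dm.data
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_feature_rejected(self):
        tree = random_tree(list("AB"), seed=0)
        t = make_table([[1, 1, 1]], list("ABX"))
        with pytest.raises(ValueError, match="absent from tree"):
            diversity.unifrac(t, tree)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        d = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        coords, prop, neg = diversity.pcoa(d)
        assert prop[0] == pytest.approx(1.0)
        recovered = np.abs(coords["PC1"].to_numpy())
        assert np.allclose(sorted(recovered), [0, 1, 1], atol=1e-9)

    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _, neg = diversity.pcoa(DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        rec = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None, :],
                             axis=2)
        assert np.allclose(rec, d, atol=1e-9)
        assert neg == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            diversity.pcoa(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


class TestPermanova:
    def euclid_dm(self, pts, ids=None):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(len(pts))])

    def test_well_separated_clusters_significant(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(3, 0.3, (20, 3))])
        dm = self.euclid_dm(pts)
        groups = ["a"] * 20 + ["b"] * 20
        res = diversity.permanova(dm, groups, n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_joint_relabeling_leaves_f_unchanged(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        dm = self.euclid_dm(pts)
        groups = ["a"] * 6 + ["b"] * 6
        f1 = diversity.permanova(dm, groups, n_perm=9, seed=0).statistic
        perm = rng.permutation(12)
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                             ids=[f"s{i}" for i in range(12)])
        f2 = diversity.permanova(dm2, [groups[i] for i in perm],
                                 n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2)

    def test_f_matches_skbio(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(1, 1, (10, 3))])
        dm = self.euclid_dm(pts)
        groups = ["a"] * 8 + ["b"] * 10
        ours = diversity.permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=groups, permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_degenerate_groups_rejected(self):
        dm = self.euclid_dm(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            diversity.permanova(dm, ["a", "a", "a", "b"], n_perm=9)


def test_compare_alpha_has_bh_family_across_indices(paper_like_bundle):
    from stomabiome import cohort as co
    kept, _ = co.apply_exclusions(paper_like_bundle.metadata,
                                  [("antibiotic_user", "yes"),
                                   ("stoma_status", "missing")])
    t = FeatureTable(paper_like_bundle.table.data.loc[kept])
    groups = paper_like_bundle.metadata.data.loc[kept, "stoma_status"]
    records = pd.concat([
        diversity.alpha_diversity(t.relabund(), "observed"),
        diversity.alpha_diversity(t.relabund(), "shannon"),
    ], ignore_index=True)
    out = diversity.compare_alpha(records, groups)
    assert set(out["metric"]) == {"observed", "shannon"}
    from stomabiome import stats
    assert np.allclose(out["fdr"], stats.benjamini_hochberg(out["p"].to_numpy()))
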