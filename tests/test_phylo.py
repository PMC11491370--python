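import io

import numpy as np
import pandas as pd
import pytest

from strepniche import phylo
from strepniche.synthetic import _simulate_tree

from conftest import tree_from_newick


@pytest.fixture(scope="module")
def three_tip_tree():
    return tree_from_newick("((A:1,B:1):2,C:3);")


@pytest.fixture(scope="module")
def star_tree():
    return tree_from_newick("(t1:1,t2:1,t3:1,t4:1);")


def random_group_tree(rng, n_tips, clustering=0.5):
    labels = [f"t{i}" for i in range(n_tips)]
    groups = ["g1" if i < n_tips // 2 else "g2" for i in range(n_tips)]
    newick = _simulate_tree(list(zip(labels, groups)), clustering, rng)
    return labels, tree_from_newick(newick), newick


class TestFaithPD:
    def test_manual_three_tip_values(self, three_tip_tree):
        assert phylo.faith_pd(three_tip_tree, ["A", "B"]) == pytest.approx(4.0)
        assert phylo.faith_pd(
            three_tip_tree, ["A", "B"], include_root=False
        ) == pytest.approx(2.0)
        assert phylo.faith_pd(three_tip_tree, ["A", "B", "C"]) == pytest.approx(7.0)

    def test_unknown_tip_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="unknown"):
            phylo.faith_pd(three_tip_tree, ["A", "Z"])

    def test_monotone_under_tip_addition(self):
        rng = np.random.default_rng(3)
        labels, tree, _ = random_group_tree(rng, 15)
        tips: list[str] = [labels[0]]
        last = phylo.faith_pd(tree, tips)
        for label in labels[1:]:
            tips.append(label)
            current = phylo.faith_pd(tree, tips)
            assert current >= last - 1e-12
            last = current

    def test_agrees_with_reference_library(self):
        from skbio import TreeNode
        from skbio.diversity.alpha import faith_pd as sk_faith_pd

        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            labels, tree, newick = random_group_tree(rng, n)
            sk_tree = TreeNode.read(io.StringIO(newick))
            tips = list(rng.choice(labels, size=int(rng.integers(1, n)), replace=False))
            counts = [1 if lab in tips else 0 for lab in labels]
            ref = sk_faith_pd(counts, taxa=labels, tree=sk_tree)
            assert phylo.faith_pd(tree, tips) == pytest.approx(ref, abs=1e-9)


class TestUnweightedUnifrac:
    def test_star_tree_reference_values(self, star_tree):
        assert phylo.unweighted_unifrac(star_tree, {"t1", "t2"}, {"t1", "t2"}) == 0.0
        assert phylo.unweighted_unifrac(star_tree, {"t1", "t2"}, {"t3", "t4"}) == 1.0
        assert phylo.unweighted_unifrac(
            star_tree, {"t1", "t2"}, {"t2", "t3"}
        ) == pytest.approx(2.0 / 3.0)

    def test_empty_group_rejected(self, star_tree):
        with pytest.raises(ValueError):
            phylo.unweighted_unifrac(star_tree, set(), {"t1"})

    def test_metric_properties_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(6, 15))
            labels, tree, _ = random_group_tree(rng, n)
            def sample():
                k = int(rng.integers(1, n))
                return set(rng.choice(labels, size=k, replace=False))
            a, b, c = sample(), sample(), sample()
            dab = phylo.unweighted_unifrac(tree, a, b)
            assert dab == pytest.approx(phylo.unweighted_unifrac(tree, b, a))
            assert 0.0 <= dab <= 1.0
            assert phylo.unweighted_unifrac(tree, a, a) == 0.0
            dac = phylo.unweighted_unifrac(tree, a, c)
            dcb = phylo.unweighted_unifrac(tree, c, b)
            assert dab <= dac + dcb + 1e-12

    def test_agrees_with_reference_library(self):
        from skbio import TreeNode
        from skbio.diversity.beta import unweighted_unifrac as sk_unifrac

        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 20))
            labels, tree, newick = random_group_tree(rng, n)
            sk_tree = TreeNode.read(io.StringIO(newick))
            a = set(rng.choice(labels, size=max(1, n // 3), replace=False))
            b = set(rng.choice(labels, size=max(1, n // 2), replace=False))
            ref = sk_unifrac(
                [1 if lab in a else 0 for lab in labels],
                [1 if lab in b else 0 for lab in labels],
                taxa=labels,
                tree=sk_tree,
            )
            assert phylo.unweighted_unifrac(tree, a, b) == pytest.approx(ref, abs=1e-9)


class TestPairwiseUnifrac:
    def test_identical_groups_give_zero_matrix(self, star_tree):
        groups = {f"g{i}": ["t1", "t2"] for i in range(4)}
        dm = phylo.pairwise_unifrac(star_tree, groups)
        assert np.allclose(dm.to_numpy(), 0.0)

    def test_two_groups_match_scalar_function(self, star_tree):
        dm = phylo.pairwise_unifrac(star_tree, {"A": ["t1", "t2"], "B": ["t2", "t3"]})
        assert dm.at["A", "B"] == pytest.approx(
            phylo.unweighted_unifrac(star_tree, {"t1", "t2"}, {"t2", "t3"})
        )
        assert dm.at["A", "A"] == 0.0


def naive_permanova_f(dist, grouping):
    """Direct SS computation from within-group distance sums."""
    n = len(grouping)
    groups = pd.unique(grouping)
    d2 = dist**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(np.asarray(grouping) == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    k = len(groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestPermanova:
    @staticmethod
    def _metric_instance(rng, n, k):
        pts = rng.normal(size=(n, 3))
        pts[: n // 2] += rng.normal(size=3)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        grouping = [f"g{i % k}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids), pd.Series(
            grouping, index=ids, name="group"
        )

    def test_pseudo_f_matches_naive_ss_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(6, 13))
            k = 2 if n < 9 else 3
            dm, grouping = self._metric_instance(rng, n, k)
            res = phylo.permanova(dm, grouping, n_permutations=9, seed=0)
            ref = naive_permanova_f(dm.to_numpy(), grouping.to_numpy())
            assert res.at["group", "pseudo_F"] == pytest.approx(ref, abs=1e-9)

    def test_identical_groups_give_p_one(self):
        # group b duplicates group a's positions exactly, so the group
        # centroids coincide and no between-group signal exists
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(4, 2))
        pts = np.vstack([pts, pts])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = pd.DataFrame(
            d, index=[f"s{i}" for i in range(8)], columns=[f"s{i}" for i in range(8)]
        )
        grouping = pd.Series(
            ["a"] * 4 + ["b"] * 4, index=dm.index, name="group"
        )
        res = phylo.permanova(dm, grouping, n_permutations=99, seed=0)
        assert res.at["group", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert res.at["group", "p"] == 1.0

    def test_seed_reproducibility_and_label_invariance(self):
        rng = np.random.default_rng(8)
        dm, grouping = self._metric_instance(rng, 12, 2)
        r1 = phylo.permanova(dm, grouping, n_permutations=99, seed=5)
        r2 = phylo.permanova(dm, grouping, n_permutations=99, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        renamed = grouping.map({"g0": "west", "g1": "east"})
        r3 = phylo.permanova(dm, renamed, n_permutations=99, seed=5)
        assert r3.at["group", "p"] == r1.at["group", "p"]
        assert r3.at["group", "pseudo_F"] == pytest.approx(
            r1.at["group", "pseudo_F"]
        )

    def test_constant_factor_rejected(self):
        dm = pd.DataFrame(
            np.zeros((4, 4)), index=list("abcd"), columns=list("abcd")
        )
        grouping = pd.Series(["g"] * 4, index=dm.index, name="group")
        with pytest.raises(ValueError, match="constant"):
            phylo.permanova(dm, grouping, n_permutations=9)

    def test_nested_terms_partition_total_ss(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(16, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(16)]
        dm = pd.DataFrame(d, index=ids, columns=ids)
        factors = pd.DataFrame(
            {
                "richness": ["m"] * 8 + ["p"] * 8,
                "fungicide": (["u"] * 4 + ["t"] * 4) * 2,
            },
            index=ids,
        )
        res = phylo.permanova(
            dm, factors, terms=["richness", ("fungicide", "richness")],
            n_permutations=49, seed=1,
        )
        parts = res.loc[["richness", "fungicide(richness)", "residual"], "sum_sq"].sum()
        assert parts == pytest.approx(res.at["total", "sum_sq"], abs=1e-9)
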