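import math

import numpy as np
import pytest

from qsevo.phylo_ancestral import (
    PhyloError,
    RootedTree,
    acctran_parsimony,
    er_log_likelihood,
    fit_er_rate,
    marginal_ancestral,
    midpoint_root,
    root_confidence_filter,
)
from qsevo.synthetic_data import gen_birth_tree, sim_trait_history

from .conftest import make_labeled_topologies
from .oracles import (
    brute_force_log_likelihood,
    brute_force_marginals,
    brute_force_parsimony_score,
)


class TestTreeBasics:
    def test_newick_roundtrip(self):
        t = RootedTree.from_newick("((A:0.3,B:0.9):0.2,C:1.1);")
        t2 = RootedTree.from_newick(t.to_newick())
        assert sorted(t2.leaf_names) == ["A", "B", "C"]
        d1 = {l.name: d for l, d in t.root_distances().items() if l.is_leaf}
        d2 = {l.name: d for l, d in t2.root_distances().items() if l.is_leaf}
        assert d1 == pytest.approx(d2)

    def test_underscores_preserved(self):
        t = RootedTree.from_newick("(og1_t1:1,og1_t2:2);")
        assert sorted(t.leaf_names) == ["og1_t1", "og1_t2"]

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(PhyloError):
            RootedTree.from_newick("((A:1,A:1):1,B:1);")


class TestMidpointRoot:
    def test_two_leaf_midpoint(self):
        t = midpoint_root("(A:1,B:3);")
        dists = sorted(d for l, d in t.root_distances().items() if l.is_leaf)
        assert dists == pytest.approx([2.0, 2.0])

    def test_balanced_four_leaf(self):
        t = midpoint_root("((A:1,B:1):1,(C:1,D:1):1);")
        dists = [d for l, d in t.root_distances().items() if l.is_leaf]
        assert dists == pytest.approx([2.0] * 4)

    def test_caterpillar_matches_all_pairs_oracle(self):
        newick = "((((A:1.0,B:2.5):0.5,C:0.7):1.2,D:3.1):0.4,E:0.9);"
        rooted = midpoint_root(newick)
        names, dmat = rooted.leaf_distance_matrix()
        # oracle: midpoint of the longest leaf-leaf path
        longest = dmat.max()
        depth = {l.name: d for l, d in rooted.root_distances().items() if l.is_leaf}
        i, j = np.unravel_index(np.argmax(dmat), dmat.shape)
        assert depth[names[i]] == pytest.approx(longest / 2, abs=1e-9)
        assert depth[names[j]] == pytest.approx(longest / 2, abs=1e-9)
        assert max(depth.values()) == pytest.approx(longest / 2, abs=1e-9)

    def test_zero_length_tree_rejected(self):
        with pytest.raises(PhyloError):
            midpoint_root("(A:0,B:0);")


class TestErLikelihood:
    def test_zero_rate_uniform_tips(self):
        t = RootedTree.from_newick("((A:1,B:1):1,C:1);")
        for k in (2, 3):
            ll = er_log_likelihood(t, {"A": 0, "B": 0, "C": 0}, k, 0.0)
            assert ll == pytest.approx(math.log(1.0 / k))

    def test_zero_rate_conflicting_tips_impossible(self):
        t = RootedTree.from_newick("((A:1,B:1):1,C:1);")
        assert er_log_likelihood(t, {"A": 0, "B": 1, "C": 0}, 2, 0.0) == -math.inf

    def test_matches_exhaustive_enumeration(self):
        t = RootedTree.from_newick("((A:0.4,B:1.3):0.6,C:0.8);")
        tips = {"A": 0, "B": 1, "C": 0}
        for q in (0.01, 0.1, 0.7, 1.0, 10.0):
            assert er_log_likelihood(t, tips, 2, q) == pytest.approx(
                brute_force_log_likelihood(t, tips, 2, q), abs=1e-10
            )

    def test_missing_tip_equivalent_to_marginalising(self):
        t = RootedTree.from_newick("((A:0.4,B:1.3):0.6,(C:0.8,D:0.3):0.2);")
        tips = {"A": 0, "B": 2, "C": 1, "D": None}
        assert er_log_likelihood(t, tips, 3, 0.5) == pytest.approx(
            brute_force_log_likelihood(t, tips, 3, 0.5), abs=1e-10
        )

    def test_leaf_order_invariance(self):
        a = RootedTree.from_newick("((A:0.4,B:1.3):0.6,C:0.8);")
        b = RootedTree.from_newick("(C:0.8,(B:1.3,A:0.4):0.6);")
        tips = {"A": 0, "B": 1, "C": 1}
        assert er_log_likelihood(a, tips, 2, 0.3) == pytest.approx(
            er_log_likelihood(b, tips, 2, 0.3), abs=1e-12
        )

    def test_negative_rate_rejected(self):
        t = RootedTree.from_newick("(A:1,B:1);")
        with pytest.raises(PhyloError):
            er_log_likelihood(t, {"A": 0, "B": 1}, 2, -0.1)


class TestFitErRate:
    def test_uniform_tips_pin_to_lower_bound(self):
        t = RootedTree.from_newick("((A:1,B:1):1,C:1);")
        q, _ = fit_er_rate(t, {"A": 0, "B": 0, "C": 0}, 2)
        assert q == pytest.approx(1e-8)

    def test_matches_dense_grid(self):
        t = RootedTree.from_newick("(((A:0.2,B:0.7):0.4,C:1.0):0.3,(D:0.5,E:0.5):0.6);")
        tips = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0}
        q, ll = fit_er_rate(t, tips, 2)
        grid = np.geomspace(1e-8, 100, 10000)
        grid_best = max(er_log_likelihood(t, tips, 2, g) for g in grid)
        assert ll >= grid_best - 1e-6

    def test_simulated_rate_recovery(self):
        # median q-hat across replicates stays within a factor 2 of truth
        estimates = []
        for rep in range(50):
            tree = gen_birth_tree(200, seed=3000 + rep, birth_rate=10.0)
            Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
            hist = sim_trait_history(tree, Q, root_state=0, seed=8000 + rep)
            tips = hist.tip_states
            if len(set(tips.values())) < 2:
                continue
            q, _ = fit_er_rate(tree, tips, 2)
            estimates.append(q)
        assert 0.5 <= float(np.median(estimates)) <= 2.0


class TestMarginalAncestral:
    def test_concordant_tips_confident_root(self):
        t = RootedTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        probs = marginal_ancestral(t, {"A": 0, "B": 0, "C": 0}, 2, 0.01)
        assert probs[t.root][0] > 0.99

    def test_vectors_normalised(self):
        t = RootedTree.from_newick("((A:0.4,B:1.3):0.6,(C:0.8,D:0.3):0.2);")
        probs = marginal_ancestral(t, {"A": 0, "B": 2, "C": 1, "D": 2}, 3, 0.4)
        for vec in probs.values():
            assert float(vec.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_observed_leaf_is_certain(self):
        t = RootedTree.from_newick("((A:0.4,B:1.3):0.6,C:0.8);")
        probs = marginal_ancestral(t, {"A": 1, "B": 0, "C": 0}, 2, 0.5)
        leaf_a = next(l for l in t.leaves() if l.name == "A")
        assert probs[leaf_a][1] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_k3(self):
        t = RootedTree.from_newick("((A:0.4,B:1.3):0.6,(C:0.8,D:0.3):0.2);")
        tips = {"A": 0, "B": 2, "C": 1, "D": 1}
        probs = marginal_ancestral(t, tips, 3, 0.5)
        oracle = brute_force_marginals(t, tips, 3, 0.5)
        for node in t.preorder():
            if not node.is_leaf:
                np.testing.assert_allclose(probs[node], oracle[id(node)], atol=1e-10)

    def test_high_rate_limit_is_flat(self):
        t = RootedTree.from_newick("((A:1,B:1):1,C:1);")
        probs = marginal_ancestral(t, {"A": 0, "B": 1, "C": 0}, 2, 1e4)
        np.testing.assert_allclose(probs[t.root], [0.5, 0.5], atol=1e-6)


class TestAcctranParsimony:
    def test_uniform_tips_zero_score(self):
        t = RootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assign, score = acctran_parsimony(t, {n: 0 for n in "ABCD"}, 2)
        assert score == 0
        assert set(assign.values()) == {0}

    def test_single_forced_change(self):
        t = RootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        _, score = acctran_parsimony(t, {"A": 0, "B": 0, "C": 1, "D": 1}, 2)
        assert score == 1

    def test_matches_exhaustive_minimum_on_six_leaf_trees(self):
        rng = np.random.default_rng(0)
        trees = make_labeled_topologies(list("ABCDEF"))
        for tree in rng.choice(len(trees), size=60, replace=False):
            t = trees[int(tree)]
            tips = {name: int(rng.integers(3)) for name in "ABCDEF"}
            _, score = acctran_parsimony(t, tips, 3)
            assert score == brute_force_parsimony_score(t, tips, 3)

    def test_multifurcation(self):
        t = RootedTree.from_newick("(A:1,B:1,C:1,D:1);")
        _, score = acctran_parsimony(t, {"A": 0, "B": 0, "C": 0, "D": 1}, 2)
        assert score == 1

    def test_missing_tips_excluded(self):
        t = RootedTree.from_newick("((A:1,B:1):1,C:1);")
        _, score = acctran_parsimony(t, {"A": 0, "B": None, "C": 0}, 2)
        assert score == 0

    def test_deterministic_output(self):
        t = RootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": 0, "B": 1, "C": 1, "D": 0}
        first = acctran_parsimony(t, tips, 2)
        for _ in range(5):
            assert acctran_parsimony(t, tips, 2) == first


class TestRootConfidenceFilter:
    @pytest.mark.parametrize(
        "probs, keep",
        [([0.60, 0.40], True), ([0.50, 0.50], False), ([0.51, 0.49], True)],
    )
    def test_threshold_semantics(self, probs, keep):
        assert root_confidence_filter(probs) is keep

    def test_unnormalised_rejected(self):
        with pytest.raises(PhyloError):
            root_confidence_filter([0.9, 0.9])
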