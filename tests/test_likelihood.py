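import itertools

import numpy as np
import pytest

from conftest import random_character_matrix, random_tree_with_lengths
from oracles import brute_force_likelihood

from exprphylo import _tree
from exprphylo.discretize import CharacterMatrix
from exprphylo.distance_trees import root_at
from exprphylo.io_formats import parse_newick
from exprphylo.likelihood import (
    MkModel,
    mk_transition_prob,
    ml_search,
    optimize_branch_lengths,
    tree_log_likelihood,
)
from exprphylo.parsimony import parsimony_search


class TestTransitionMatrix:
    def test_zero_branch_is_identity(self):
        assert np.allclose(mk_transition_prob(0.0), np.eye(3))

    def test_long_branch_is_uniform(self):
        assert np.allclose(mk_transition_prob(500.0), np.full((3, 3), 1 / 3))

    def test_rows_sum_to_one_and_same_prob_decreases(self):
        prev = 1.0
        for b in [0.0, 0.1, 0.5, 1.0, 3.0]:
            p = mk_transition_prob(b)
            assert np.allclose(p.sum(axis=1), 1.0)
            assert p[0, 0] <= prev
            prev = p[0, 0]

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            mk_transition_prob(-0.1)


class TestPruning:
    def test_two_taxon_closed_form(self):
        b = 0.7
        tree = parse_newick(f"(A:{b / 2},B:{b / 2});", rooted=True)
        cm = CharacterMatrix(taxa=["A", "B"], states=np.array([[1], [1]]))
        expected = np.log((1 / 3) * mk_transition_prob(b)[0, 0])
        assert tree_log_likelihood(tree, cm) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_pattern_probabilities_sum_to_one(self, rng, n):
        labels = [f"T{i}" for i in range(n)]
        tree = random_tree_with_lengths(rng, labels, 0.05, 1.5)
        total = 0.0
        for pattern in itertools.product((0, 1, 2), repeat=n):
            cm = CharacterMatrix(
                taxa=labels, states=np.array(pattern).reshape(n, 1)
            )
            total += np.exp(tree_log_likelihood(tree, cm))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_internal_summation(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 6))
            labels = [f"T{i}" for i in range(n)]
            tree = random_tree_with_lengths(rng, labels, 0.05, 2.0)
            cm = random_character_matrix(rng, n, 4, labels=labels)
            ours = tree_log_likelihood(tree, cm)
            brute = brute_force_likelihood(
                tree, cm.taxa, cm.states, mk_transition_prob
            )
            assert ours == pytest.approx(brute, abs=1e-10)

    def test_invariant_to_rerooting(self, rng):
        labels = [f"T{i}" for i in range(5)]
        tree = random_tree_with_lengths(rng, labels, 0.1, 1.0)
        cm = random_character_matrix(rng, 5, 6, labels=labels)
        base = tree_log_likelihood(tree, cm)
        for leaf in labels[:3]:
            rerooted = root_at(tree, leaf)
            assert tree_log_likelihood(rerooted, cm) == pytest.approx(base, abs=1e-8)

    def test_missing_branch_length_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        cm = CharacterMatrix(taxa=list("ABCD"), states=np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="branch length"):
            tree_log_likelihood(tree, cm)


class TestBranchOptimization:
    def test_constant_matrix_shrinks_lengths_to_zero(self):
        tree = parse_newick("((A:0.5,B:0.5):0.2,(C:0.3,D:0.1):0.2);")
        cm = CharacterMatrix(taxa=list("ABCD"), states=np.ones((4, 20), dtype=np.int8))
        opt, ll = optimize_branch_lengths(tree, cm)
        for node in opt.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length == pytest.approx(0.0, abs=1e-4)
        assert ll == pytest.approx(20 * np.log(1 / 3), abs=1e-3)

    def test_two_taxon_optimum_solves_closed_form(self):
        # fraction f of characters differ; the MLE total length solves
        # P_same(b) = 1 - f  =>  b = -(2/3) log((3(1-f) - 1)/2)
        f = 0.25
        n = 40
        diff = int(f * n)
        states = np.zeros((2, n), dtype=np.int8)
        states[1, :diff] = 2
        cm = CharacterMatrix(taxa=["A", "B"], states=states)
        tree = parse_newick("(A:0.2,B:0.2);", rooted=True)
        opt, _ = optimize_branch_lengths(tree, cm)
        total = sum(
            nd.edge.length for nd in opt.preorder_node_iter() if nd.parent_node
        )
        expected = -(2 / 3) * np.log((3 * (1 - f) - 1) / 2)
        assert total == pytest.approx(expected, abs=1e-4)

    def test_duplicating_characters_keeps_optimum(self):
        states = np.array([[0, 0, 2], [0, 2, 2]], dtype=np.int8)
        cm1 = CharacterMatrix(taxa=["A", "B"], states=states)
        cm2 = CharacterMatrix(taxa=["A", "B"], states=np.hstack([states, states]))
        tree = parse_newick("(A:0.2,B:0.2);", rooted=True)
        t1, _ = optimize_branch_lengths(tree, cm1)
        t2, _ = optimize_branch_lengths(tree, cm2)
        tot1 = sum(n.edge.length for n in t1.preorder_node_iter() if n.parent_node)
        tot2 = sum(n.edge.length for n in t2.preorder_node_iter() if n.parent_node)
        assert tot1 == pytest.approx(tot2, abs=1e-3)


class TestMlSearch:
    def test_clean_split_signal_recovers_quartet(self):
        states = np.tile(np.array([[2], [2], [0], [0]]), (1, 25))
        # add constant characters so pendant branches stay short
        states = np.hstack([states, np.ones((4, 75), dtype=np.int8)])
        cm = CharacterMatrix(taxa=list("ABCD"), states=states)
        res = ml_search(cm, strategy="exhaustive")
        assert _tree.splits(res.best_tree) == {frozenset({"C", "D"})}

    def test_uninformative_character_flat_over_topologies(self):
        cm = CharacterMatrix(taxa=list("ABCD"), states=np.ones((4, 3), dtype=np.int8))
        lls = []
        for topo in _tree.all_unrooted_topologies(4):
            tree = _tree.snode_to_dendropy(topo, list("ABCD"), default_length=0.1)
            lls.append(tree_log_likelihood(tree, cm))
        assert max(lls) - min(lls) < 1e-6

    def test_ml_and_parsimony_agree_on_clean_signal(self):
        # two nested splits, no homoplasy
        block1 = np.tile(np.array([[2], [2], [0], [0], [0]]), (1, 10))
        block2 = np.tile(np.array([[1], [1], [1], [2], [2]]), (1, 10))
        const = np.ones((5, 40), dtype=np.int8)
        cm = CharacterMatrix(
            taxa=list("ABCDE"), states=np.hstack([block1, block2, const])
        )
        mp = parsimony_search(cm, strategy="exhaustive")
        ml = ml_search(cm, strategy="exhaustive")
        assert _tree.splits(ml.best_tree) == _tree.splits(mp.best_tree)

    def test_simulation_recovers_topology(self, rng):
        """Data simulated on a known 6-taxon tree recovers it (most seeds)."""
        from exprphylo.support_and_compare import rf_distance

        labels = [f"T{i}" for i in range(6)]
        true = parse_newick("(((T0,T1),T2),(T3,(T4,T5)));")
        for node in true.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.2
        model = MkModel()
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            states = _simulate_on_tree(true, labels, 500, model, rng)
            cm = CharacterMatrix(taxa=labels, states=states)
            res = ml_search(cm, strategy="nni_from_nj")
            hits += rf_distance(res.best_tree, true) == 0
        assert hits >= int(0.9 * n_rep)


def _simulate_on_tree(tree, labels, n_chars, model, rng):
    idx = {t: i for i, t in enumerate(labels)}
    states = np.zeros((len(labels), n_chars), dtype=np.int8)
    node_state = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_state[node] = rng.integers(0, 3, size=n_chars)
        else:
            p = model.transition(node.edge.length)
            prev = node_state[node.parent_node]
            draw = rng.random(n_chars)
            cum = np.cumsum(p[prev, :], axis=1)
            node_state[node] = (draw[:, None] > cum).sum(axis=1)
        if node.is_leaf():
            states[idx[node.taxon.label]] = node_state[node]
    return states
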