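"""Maximum likelihood under a symmetric 3-state Markov model (Mk, k=3).

The model is the 3-state analogue of Jukes-Cantor: equal stationary
frequencies (1/3) and a single exchange rate, with branch lengths measured
in expected state changes per character.  The transition probability has
the closed form

    P_same(b) = 1/3 + (2/3) exp(-1.5 b),      P_diff(b) = (1 - P_same(b)) / 2.

Likelihoods are computed with Felsenstein's pruning algorithm; the model is
time-reversible, so the likelihood does not depend on the rooting (pulley
principle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from . import _tree
from ._tree import SNode
from .discretize import CharacterMatrix
from .parsimony import character_distance_matrix
from .distance_trees import neighbor_joining

__all__ = [
    "MkModel",
    "mk_transition_prob",
    "tree_log_likelihood",
    "optimize_branch_lengths",
    "ml_search",
    "MlResult",
    "MAX_EXHAUSTIVE_TAXA_ML",
]

MAX_EXHAUSTIVE_TAXA_ML = 7
BRANCH_UPPER = 10.0  # P_same(10) ~ 1/3: longer branches are unidentifiable
BRANCH_TOL = 1e-6
SWEEP_TOL = 1e-8
MAX_SWEEPS = 50


@dataclass(frozen=True)
class MkModel:
    """Symmetric k-state Markov model; only k=3 is used here."""

    k: int = 3

    @property
    def stationary(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)

    def transition(self, b: float) -> np.ndarray:
        return mk_transition_prob(b, k=self.k)


def mk_transition_prob(b: float, k: int = 3) -> np.ndarray:
    """Transition matrix after branch length ``b`` (expected changes/char)."""
    if b < 0:
        raise ValueError("branch length must be >= 0")
    p_same = 1.0 / k + ((k - 1.0) / k) * np.exp(-k * b / (k - 1.0))
    p_diff = (1.0 - p_same) / (k - 1.0)
    p = np.full((k, k), p_diff)
    np.fill_diagonal(p, p_same)
    return p


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _pattern_weights(states: np.ndarray):
    uniq, counts = np.unique(states.T, axis=0, return_counts=True)
    return uniq.T.copy(), counts.astype(float)


def _prune_snode(root: SNode, states: np.ndarray, model: MkModel) -> np.ndarray:
    """Per-character log-likelihood at the root (uniform root prior)."""
    k = model.k
    nchar = states.shape[1]
    partial: dict[int, np.ndarray] = {}
    scale: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            arr = np.zeros((nchar, k))
            arr[np.arange(nchar), states[node.taxon]] = 1.0
            partial[id(node)] = arr
            scale[id(node)] = np.zeros(nchar)
            continue
        acc = np.ones((nchar, k))
        logscale = np.zeros(nchar)
        for c in node.children:
            if c.length is None:
                raise ValueError("missing branch length on an edge")
            p = model.transition(c.length)
            acc = acc * (partial.pop(id(c)) @ p.T)
            logscale += scale.pop(id(c))
        m = acc.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        acc = acc / safe[:, None]
        logscale += np.log(safe)
        partial[id(node)] = acc
        scale[id(node)] = logscale
    top = partial[id(root)]
    return np.log(top @ model.stationary) + scale[id(root)]


def _check_tree_matrix(tree: dendropy.Tree, cm: CharacterMatrix) -> dict:
    tree_taxa = set(_tree.leaf_labels(tree))
    cm_taxa = set(cm.taxa)
    if tree_taxa != cm_taxa:
        raise ValueError(
            "tree leaves and matrix taxa differ; symmetric difference: "
            f"{sorted(tree_taxa ^ cm_taxa)}"
        )
    return {t: i for i, t in enumerate(cm.taxa)}


def tree_log_likelihood(
    tree: dendropy.Tree, cm: CharacterMatrix, model: MkModel | None = None
) -> float:
    """Log-likelihood of the character matrix on the tree (characters i.i.d.)."""
    model = model or MkModel()
    index_of = _check_tree_matrix(tree, cm)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("missing branch length on an edge")
    root = _tree.dendropy_to_snode(tree, index_of)
    states, weights = _pattern_weights(cm.states)
    ll = _prune_snode(root, states, model)
    return float((ll * weights).sum())


def optimize_branch_lengths(
    tree: dendropy.Tree,
    cm: CharacterMatrix,
    model: MkModel | None = None,
) -> tuple[dendropy.Tree, float]:
    """Optimize branch lengths on a fixed topology.

    Coordinate-wise bounded Brent on each edge (bounds [0, 10], tol 1e-6),
    sweeping until the log-likelihood gain drops below 1e-8 or 50 sweeps.
    Returns (tree clone with optimized lengths, final log-likelihood).
    """
    model = model or MkModel()
    tree = tree.clone(depth=1)
    index_of = _check_tree_matrix(tree, cm)
    root = _tree.dendropy_to_snode(tree, index_of)
    snodes = [n for n in root.postorder() if n is not root]
    for n in snodes:
        if n.length is None or n.length < 0:
            n.length = 0.1
    states, weights = _pattern_weights(cm.states)

    def total_ll() -> float:
        return float((_prune_snode(root, states, model) * weights).sum())

    cur = total_ll()
    if not np.isfinite(cur):
        raise ValueError("non-finite likelihood at the starting lengths")
    for _ in range(MAX_SWEEPS):
        before = cur
        for idx, node in enumerate(snodes):
            def neg(b, node=node):
                node.length = b
                return -float((_prune_snode(root, states, model) * weights).sum())

            res = minimize_scalar(
                neg, bounds=(0.0, BRANCH_UPPER), method="bounded",
                options={"xatol": BRANCH_TOL},
            )
            if not np.isfinite(res.fun):
                raise ValueError(f"non-finite likelihood while optimizing edge {idx}")
            # keep the optimum only if it does not decrease the likelihood
            if -res.fun >= cur - 1e-12:
                node.length = float(res.x)
                cur = -float(res.fun)
            else:
                node.length = node.length
                cur = -neg(node.length, node)
        if cur - before < SWEEP_TOL:
            break
    # write lengths back onto the dendropy clone (parallel structure walk)
    def write_back(dnode, snode):
        for dc, sc in zip(dnode.child_nodes(), snode.children):
            dc.edge.length = float(sc.length)
            write_back(dc, sc)

    write_back(tree.seed_node, root)
    return tree, cur


@dataclass
class MlResult:
    """Best topology with optimized lengths and its log-likelihood."""

    best_tree: dendropy.Tree
    log_likelihood: float
    strategy: str
    n_evaluated: int
    newick: str = field(default="")


def _optimize_snode(
    root: SNode,
    states: np.ndarray,
    weights: np.ndarray,
    model: MkModel,
    max_sweeps: int = MAX_SWEEPS,
    xatol: float = BRANCH_TOL,
) -> float:
    """In-place branch-length optimization on a search tree; returns logL."""
    snodes = [n for n in root.postorder() if n is not root]
    for n in snodes:
        if not n.length or n.length < 0:
            n.length = 0.1

    def total() -> float:
        return float((_prune_snode(root, states, model) * weights).sum())

    cur = total()
    for _ in range(max_sweeps):
        before = cur
        for node in snodes:
            def neg(b, node=node):
                node.length = b
                return -total()

            res = minimize_scalar(
                neg, bounds=(0.0, BRANCH_UPPER), method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= cur:
                node.length = float(res.x)
                cur = -float(res.fun)
            else:
                cur = -neg(node.length, node)
        if cur - before < SWEEP_TOL:
            break
    return cur


def ml_search(
    cm: CharacterMatrix,
    strategy: str = "exhaustive",
    model: MkModel | None = None,
) -> MlResult:
    """Search topologies by optimized log-likelihood.

    ``exhaustive`` (n <= 7) optimizes branch lengths on every unrooted
    topology; ``nni_from_nj`` hill-climbs by NNI from the NJ tree on
    p-distances.
    """
    model = model or MkModel()
    n = cm.n_taxa
    if n < 4:
        raise ValueError("ML search needs >= 4 taxa")
    states, weights = _pattern_weights(cm.states)
    names = list(cm.taxa)

    def finish(snode_root, ll, strategy, n_eval):
        tree = _tree.snode_to_dendropy(snode_root, names, unroot=True)
        return MlResult(
            best_tree=tree,
            log_likelihood=ll,
            strategy=strategy,
            n_evaluated=n_eval,
            newick=tree.as_string(schema="newick", suppress_rooting=True).strip(),
        )

    if strategy == "exhaustive":
        if n > MAX_EXHAUSTIVE_TAXA_ML:
            raise ValueError(
                f"exhaustive ML search is limited to {MAX_EXHAUSTIVE_TAXA_ML} "
                f"taxa (got {n}); use strategy='nni_from_nj'"
            )
        best_ll, best_root, n_eval = -np.inf, None, 0
        for topo in _tree.all_unrooted_topologies(n):
            n_eval += 1
            work = _tree.clone(topo)
            ll = _optimize_snode(work, states, weights, model, max_sweeps=4, xatol=1e-4)
            if ll > best_ll + 1e-12:
                best_ll, best_root = ll, work
        best_ll = _optimize_snode(best_root, states, weights, model)
        return finish(best_root, best_ll, "exhaustive", n_eval)

    if strategy == "nni_from_nj":
        start = neighbor_joining(character_distance_matrix(cm))
        index_of = {t: i for i, t in enumerate(names)}
        from .parsimony import _rooted_at_zero

        current = _rooted_at_zero(_tree.dendropy_to_snode(start, index_of))
        cur_ll = _optimize_snode(current, states, weights, model, max_sweeps=4, xatol=1e-4)
        n_eval = 1
        improved = True
        while improved:
            improved = False
            for nb in _tree.nni_neighbors(current):
                n_eval += 1
                ll = _optimize_snode(nb, states, weights, model, max_sweeps=4, xatol=1e-4)
                if ll > cur_ll + 1e-9:
                    current, cur_ll = nb, ll
                    improved = True
                    break
        cur_ll = _optimize_snode(current, states, weights, model)
        return finish(current, cur_ll, "nni_from_nj", n_eval)

    raise ValueError(f"unknown strategy {strategy!r}; options: exhaustive, nni_from_nj")
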