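"""Fitch parsimony scoring and tree search over 3-state character matrices.

The Fitch algorithm computes, per character, the minimum number of state
changes a topology requires, by post-order state-set intersection; the
score is independent of the rooting.  Search is either exhaustive (all
(2n-5)!! unrooted topologies, n <= 9) or a nearest-neighbor-interchange
hill climb started from the Neighbor-Joining tree on mean character
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import _tree
from ._tree import SNode
from .discretize import CharacterMatrix, informative_mask
from .distance_trees import DistanceMatrix, neighbor_joining

__all__ = [
    "ParsimonyResult",
    "fitch_score",
    "parsimony_search",
    "character_distance_matrix",
    "MAX_EXHAUSTIVE_TAXA",
]

MAX_EXHAUSTIVE_TAXA = 9


def _leaf_masks(cm: CharacterMatrix) -> np.ndarray:
    """Per-taxon state-set bitmasks, shape (n_taxa, n_characters)."""
    return (np.uint8(1) << cm.states.astype(np.uint8)).astype(np.uint8)


def _fitch_snode(root: SNode, masks: np.ndarray, weights: np.ndarray | None = None) -> int:
    """Total Fitch changes of the (possibly multifurcating-root) tree."""
    nchar = masks.shape[1]
    total = np.zeros(nchar, dtype=np.int64)
    node_mask: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            node_mask[id(node)] = masks[node.taxon]
            continue
        acc = None
        for c in node.children:
            m = node_mask.pop(id(c))
            if acc is None:
                acc = m
                continue
            inter = acc & m
            empty = inter == 0
            total += empty
            acc = np.where(empty, acc | m, inter)
        node_mask[id(node)] = acc
    if weights is not None:
        return int((total * weights).sum())
    return int(total.sum())


def fitch_score(tree: dendropy.Tree, cm: CharacterMatrix) -> int:
    """Minimum-mutation (Fitch) score of ``cm`` on the given topology."""
    tree_taxa = set(_tree.leaf_labels(tree))
    cm_taxa = set(cm.taxa)
    if tree_taxa != cm_taxa:
        raise ValueError(
            "tree leaves and matrix taxa differ; symmetric difference: "
            f"{sorted(tree_taxa ^ cm_taxa)}"
        )
    index_of = {t: i for i, t in enumerate(cm.taxa)}
    root = _tree.dendropy_to_snode(tree, index_of)
    return _fitch_snode(root, _leaf_masks(cm))


def character_distance_matrix(cm: CharacterMatrix) -> DistanceMatrix:
    """Mean character difference (p-distance) between taxa."""
    s = cm.states
    diff = (s[:, None, :] != s[None, :, :]).mean(axis=2)
    return DistanceMatrix(ids=list(cm.taxa), values=diff, metric="p_distance")


@dataclass
class ParsimonyResult:
    """Best tree(s) found, their shared score, and search bookkeeping."""

    best_trees: list
    score: int
    strategy: str
    n_evaluated: int
    newicks: list[str] = field(default_factory=list)

    @property
    def best_tree(self) -> dendropy.Tree:
        return self.best_trees[0]


def _compress_patterns(masks: np.ndarray):
    """Aggregate identical character columns; returns (masks, weights)."""
    cols = masks.T
    uniq, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return uniq.T.copy(), counts.astype(np.int64)


def parsimony_search(
    cm: CharacterMatrix,
    strategy: str = "exhaustive",
    max_trees: int = 100,
) -> ParsimonyResult:
    """Find minimum-Fitch-score topologies.

    ``exhaustive`` enumerates every unrooted topology (n <= 9 taxa) and
    returns all co-optimal trees (capped at ``max_trees``); ``nni_from_nj``
    hill-climbs by NNI from the NJ tree on p-distances, keeping the first
    tree of each improving score and stopping at a local optimum.

    Uninformative characters add a topology-independent constant, so the
    search scores only informative characters and adds the constant back.
    """
    n = cm.n_taxa
    if n < 4:
        raise ValueError("parsimony search needs >= 4 taxa")
    masks = _leaf_masks(cm)
    info = informative_mask(cm.states)
    # constant contribution of uninformative characters: (#states - 1) each
    n_states_per_char = np.stack([(cm.states == s).any(axis=0) for s in (0, 1, 2)]).sum(axis=0)
    base = int((n_states_per_char[~info] - 1).sum())
    masks_info, weights = _compress_patterns(masks[:, info])
    if masks_info.shape[1] == 0:
        masks_info = np.ones((n, 1), dtype=np.uint8)
        weights = np.zeros(1, dtype=np.int64)

    if strategy == "exhaustive":
        if n > MAX_EXHAUSTIVE_TAXA:
            raise ValueError(
                f"exhaustive search is limited to {MAX_EXHAUSTIVE_TAXA} taxa "
                f"(got {n}); use strategy='nni_from_nj'"
            )
        best = None
        best_trees: list[SNode] = []
        n_eval = 0
        for topo in _tree.all_unrooted_topologies(n):
            n_eval += 1
            s = _fitch_snode(topo, masks_info, weights)
            if best is None or s < best:
                best = s
                best_trees = [_tree.clone(topo)]
            elif s == best and len(best_trees) < max_trees:
                best_trees.append(_tree.clone(topo))
        trees = [
            _tree.snode_to_dendropy(t, list(cm.taxa), unroot=True) for t in best_trees
        ]
        return ParsimonyResult(
            best_trees=trees,
            score=int(best) + base,
            strategy="exhaustive",
            n_evaluated=n_eval,
            newicks=[_newick_topo(t) for t in trees],
        )

    if strategy == "nni_from_nj":
        start_dm = character_distance_matrix(cm)
        start = neighbor_joining(start_dm)
        index_of = {t: i for i, t in enumerate(cm.taxa)}
        current = _rooted_at_zero(_tree.dendropy_to_snode(start, index_of))
        cur_score = _fitch_snode(current, masks_info, weights)
        n_eval = 1
        improved = True
        while improved:
            improved = False
            for nb in _tree.nni_neighbors(current):
                n_eval += 1
                s = _fitch_snode(nb, masks_info, weights)
                if s < cur_score:
                    current, cur_score = nb, s
                    improved = True
                    break  # greedy: restart from the improved tree
        tree = _tree.snode_to_dendropy(current, list(cm.taxa), unroot=True)
        return ParsimonyResult(
            best_trees=[tree],
            score=int(cur_score) + base,
            strategy="nni_from_nj",
            n_evaluated=n_eval,
            newicks=[_newick_topo(tree)],
        )

    raise ValueError(f"unknown strategy {strategy!r}; options: exhaustive, nni_from_nj")


def _newick_topo(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=True,
        unquoted_underscores=True,
    ).strip()


def _rooted_at_zero(root: SNode) -> SNode:
    """Re-shape an arbitrary(-degree) unrooted SNode tree into the canonical
    rooted-at-taxon-0 binary search form used by the NNI machinery."""
    # collect edges as adjacency, then rebuild rooted at the taxon-0 leaf
    adj: dict[int, list[int]] = {}
    taxon: dict[int, int | None] = {}
    counter = [0]

    def visit(node, parent_key):
        key = counter[0]
        counter[0] += 1
        taxon[key] = node.taxon
        adj.setdefault(key, [])
        if parent_key is not None:
            adj[key].append(parent_key)
            adj[parent_key].append(key)
        for c in node.children:
            visit(c, key)

    visit(root, None)
    zero = next(k for k, t in taxon.items() if t == 0)
    new_root = SNode()
    new_root.add(SNode(taxon=0))

    def build(key, parent_key):
        node = SNode(taxon=taxon[key])
        for nb in adj[key]:
            if nb != parent_key:
                node.add(build(nb, key))
        return node

    attach = adj[zero][0]
    sub = build(attach, zero)
    sub = _binarize(sub)
    new_root.add(sub)
    return new_root


def _binarize(node: SNode) -> SNode:
    """Resolve polytomies arbitrarily (left-combining) to obtain a binary tree."""
    node.children = [_binarize(c) for c in node.children]
    for c in node.children:
        c.parent = node
    while len(node.children) > 2:
        a = node.children.pop(0)
        b = node.children.pop(0)
        mid = SNode()
        mid.add(a)
        mid.add(b)
        node.children.insert(0, mid)
        mid.parent = node
    # suppress degree-2 internal nodes created upstream
    if len(node.children) == 1 and node.taxon is None:
        only = node.children[0]
        only.parent = node.parent
        return only
    return node
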