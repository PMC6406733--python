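"""Bootstrap support, hierarchical-clustering baselines and tree comparison.

Support values are character (or gene) bootstrap percentages mapped onto
the point-estimate tree; the comparison layer provides single/complete
linkage dendrograms, a temporal-order score (Kendall tau-b between each
leaf's time rank and its divergence order from the root) and the
Robinson-Foulds distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau

from . import _tree
from .discretize import CharacterMatrix
from .distance_trees import DistanceMatrix, compute_distance, neighbor_joining, root_at
from .io_formats import ExpressionMatrix
from .parsimony import character_distance_matrix, parsimony_search
from .likelihood import ml_search

__all__ = [
    "SupportTree",
    "bootstrap_support",
    "hierarchical_cluster",
    "temporal_order_score",
    "rf_distance",
]


@dataclass
class SupportTree:
    """Point-estimate tree with per-internal-edge bootstrap percentages.

    ``supports`` maps each non-trivial split (frozenset of leaf labels, the
    side not containing the reference leaf) to an integer percent in
    [0, 100]; the same values are written onto the internal node labels of
    ``tree`` for Newick output.
    """

    tree: dendropy.Tree
    supports: dict
    n_reps: int
    method: str
    seed: int | None = None

    def support_of(self, split: frozenset) -> int | None:
        return self.supports.get(split)


def _infer(method: str, data, metric: str, strategy: str) -> dendropy.Tree:
    if method == "nj":
        if isinstance(data, ExpressionMatrix):
            return neighbor_joining(compute_distance(data, metric=metric))
        if isinstance(data, CharacterMatrix):
            return neighbor_joining(character_distance_matrix(data))
        if isinstance(data, DistanceMatrix):
            return neighbor_joining(data)
        raise ValueError("nj bootstrap needs an expression or character matrix")
    if method == "parsimony":
        return parsimony_search(data, strategy=strategy).best_tree
    if method == "ml":
        return ml_search(data, strategy=strategy).best_tree
    raise ValueError(f"unknown method {method!r}; options: nj, parsimony, ml")


def _resample(data, rng: np.random.Generator):
    """Resample characters (genes) with replacement."""
    if isinstance(data, ExpressionMatrix):
        idx = rng.integers(0, data.n_genes, size=data.n_genes)
        vals = data.values.iloc[idx].reset_index(drop=True)
        vals.index = [f"g{i}" for i in range(len(vals))]
        return ExpressionMatrix(vals, data.sample_meta.copy(), data.log_scale)
    if isinstance(data, CharacterMatrix):
        idx = rng.integers(0, data.n_characters, size=data.n_characters)
        return CharacterMatrix(
            taxa=list(data.taxa), states=data.states[:, idx], tau=data.tau
        )
    raise ValueError("bootstrap needs an expression or character matrix")


def bootstrap_support(
    data,
    method: str = "nj",
    n_reps: int = 100,
    seed: int | None = None,
    metric: str = "euclidean",
    strategy: str = "nni_from_nj",
) -> SupportTree:
    """Character-bootstrap support for the point-estimate tree.

    Genes (expression rows) or characters are resampled with replacement
    ``n_reps`` times; each edge's support is the percentage of replicate
    trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = _infer(method, data, metric, strategy)
    point_splits = _tree.splits(point)
    hits = {s: 0 for s in point_splits}
    for _ in range(n_reps):
        rep_tree = _infer(method, _resample(data, rng), metric, strategy)
        rep_splits = _tree.splits(rep_tree)
        for s in point_splits:
            if s in rep_splits:
                hits[s] += 1
    supports = {s: int(round(100.0 * h / n_reps)) for s, h in hits.items()}
    _annotate(point, supports)
    return SupportTree(
        tree=point, supports=supports, n_reps=n_reps, method=method, seed=seed
    )


def _annotate(tree: dendropy.Tree, supports: dict) -> None:
    all_leaves = frozenset(_tree.leaf_labels(tree))
    ref = min(all_leaves)
    below = _tree._node_leafsets(tree)
    for node, s in below.items():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = all_leaves - s if ref in s else s
        if side in supports:
            node.label = str(supports[side])


def hierarchical_cluster(dm: DistanceMatrix, linkage_method: str = "single") -> dendropy.Tree:
    """Single or complete linkage dendrogram as a rooted ultrametric tree."""
    if linkage_method not in ("single", "complete"):
        raise ValueError(
            f"unknown linkage {linkage_method!r}; options: single, complete"
        )
    if dm.n < 2:
        raise ValueError("need >= 2 taxa to cluster")
    z = linkage(squareform(dm.values, checks=False), method=linkage_method)
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    heights = []
    for label in dm.ids:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(label)
        nodes.append(nd)
        heights.append(0.0)
    for a, b, h, _ in z:
        parent = dendropy.Node()
        for child in (nodes[int(a)], nodes[int(b)]):
            parent.add_child(child)
        h = float(h)
        nodes[int(a)].edge.length = h - heights[int(a)]
        nodes[int(b)].edge.length = h - heights[int(b)]
        nodes.append(parent)
        heights.append(h)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[-1]
    tree.is_rooted = True
    return tree


def _divergence_orders(tree: dendropy.Tree) -> dict:
    """Leaf -> depth (edge count from the root) of the node where the
    leaf's lineage branches off the root path."""
    depth = {tree.seed_node: 0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + 1
    return {
        lf.taxon.label: depth[lf.parent_node] for lf in tree.leaf_node_iter()
    }


def temporal_order_score(tree: dendropy.Tree, time_rank: dict) -> float:
    """Kendall tau-b between leaf time ranks and divergence order.

    Requires a rooted tree (bifurcating root).  +1 means the rooted tree is
    a caterpillar that peels leaves off in exact time order; -1 the exact
    reverse; ~0 means no temporal signal.
    """
    if not tree.is_rooted or len(tree.seed_node.child_nodes()) != 2:
        raise ValueError("temporal_order_score requires a rooted (bifurcating) tree")
    orders = _divergence_orders(tree)
    labels = sorted(orders)
    missing = [l for l in labels if l not in time_rank]
    if missing:
        raise ValueError(f"missing time rank for leaves: {missing}")
    x = [time_rank[l] for l in labels]
    y = [orders[l] for l in labels]
    tau, _ = kendalltau(x, y)
    return float(tau)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference of non-trivial bipartitions."""
    l1, l2 = set(_tree.leaf_labels(t1)), set(_tree.leaf_labels(t2))
    if l1 != l2:
        raise ValueError(
            f"trees have different leaf sets; symmetric difference: {sorted(l1 ^ l2)}"
        )
    s1, s2 = _tree.splits(t1), _tree.splits(t2)
    return len(s1 ^ s2)
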