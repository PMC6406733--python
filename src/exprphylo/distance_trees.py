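"""Distance matrices over expression profiles and Neighbor-Joining trees.

Samples are the taxa; the distance between two samples is computed over all
genes.  NJ follows Saitou & Nei's agglomeration with the Studier-Keppler Q
criterion, which is consistent on additive matrices: when the input equals
the path-length matrix of some tree, that tree (topology and branch
lengths) is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._tree import _node_leafsets, leaf_labels
from .io_formats import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "compute_distance",
    "neighbor_joining",
    "root_at",
    "METRICS",
]

METRICS = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "one_minus_pearson": "correlation",
}


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match matrix size")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric (tol 1e-9)")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


def compute_distance(expr: ExpressionMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise sample-sample distances over all genes."""
    if metric not in METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; options: {', '.join(sorted(METRICS))}"
        )
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples for a distance matrix")
    x = expr.values.to_numpy(dtype=float).T  # samples x genes
    d = squareform(pdist(x, metric=METRICS[metric]))
    d = np.clip(d, 0.0, None)  # 'correlation' can go -eps numerically
    return DistanceMatrix(ids=list(expr.sample_ids), values=d, metric=metric)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor Joining.

    Ties on the Q criterion resolve to the lexicographically smallest index
    pair (determinism); negative branch lengths are clamped to zero with
    the deficit transferred to the sibling edge.  Returns an unrooted tree
    (trifurcating seed node).
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    for label in dm.ids:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(label)
        nodes.append(nd)
    d = dm.values.copy()
    active = list(range(n))  # indices into rows of d / entries of nodes

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among minima
        flat = np.argwhere(q == q.min())
        ii, jj = min((min(a, b), max(a, b)) for a, b in flat)
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2)) if m > 2 else 0.5 * dij
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = float(length)
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        d = np.hstack([d, new_col[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    tree = dendropy.Tree(taxon_namespace=tns)
    if len(active) == 2:
        i, j = active
        dij = d[i, j]
        # join the last two clusters on a single edge through the seed node
        a, b = nodes[i], nodes[j]
        if not b.is_leaf():
            a, b = b, a  # prefer an internal node as the attachment point
        if a.is_leaf():  # n == 2 cannot happen (guarded), keep general anyway
            tree.seed_node.add_child(a)
            tree.seed_node.add_child(b)
            a.edge.length = b.edge.length = dij / 2.0
        else:
            a.add_child(b)
            b.edge.length = float(max(dij, 0.0))
            tree.seed_node = a
    else:
        tree.seed_node = nodes[active[0]]
    tree.is_rooted = False
    return tree


def root_at(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root the tree on the edge separating the outgroup from everything else.

    ``outgroup`` is a leaf label or an iterable of labels; the set must be
    monophyletic in the unrooted tree.  The subtending edge length is split
    50/50 across the new root.
    """
    if isinstance(outgroup, str):
        og = frozenset([outgroup])
    else:
        og = frozenset(outgroup)
    tree = tree.clone(depth=1)
    all_leaves = frozenset(leaf_labels(tree))
    unknown = og - all_leaves
    if unknown:
        raise ValueError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if og == all_leaves:
        raise ValueError("outgroup cannot be the entire leaf set")
    below = _node_leafsets(tree)
    target = None
    for node, s in below.items():
        if node.parent_node is None:
            continue
        if s == og or (all_leaves - s) == og:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic in the unrooted tree"
        )
    length = target.edge.length
    half = None if length is None else length / 2.0
    tree.reroot_at_edge(target.edge, update_bipartitions=False)
    # reroot_at_edge puts the new root on the edge; split its length evenly
    for child in tree.seed_node.child_nodes():
        child.edge.length = half
    tree.is_rooted = True
    return tree
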