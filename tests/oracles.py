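"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (full enumeration, direct formulas)
and shares no code with the package's algorithms.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Trees as edge lists (leaves are labels, internals are ints >= 0)
# ---------------------------------------------------------------------------

def dendropy_edges(tree):
    """Edge list [(parent_key, child_key)] plus leaf-key -> label map."""
    keys = {}
    labels = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[node] = i
        if node.is_leaf():
            labels[i] = node.taxon.label
    edges = [
        (keys[n.parent_node], keys[n])
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    return edges, labels


def brute_force_fitch(tree, taxa, states_matrix):
    """Minimum changes by enumerating every internal-node state assignment.

    Vectorized over assignments and characters, but still a full
    enumeration — no dynamic programming.
    """
    edges, leaf_labels = dendropy_edges(tree)
    all_keys = sorted({k for e in edges for k in e})
    internal = [k for k in all_keys if k not in leaf_labels]
    state_of_taxon = {t: i for i, t in enumerate(taxa)}
    nchar = states_matrix.shape[1]
    assigns = np.array(
        list(itertools.product((0, 1, 2), repeat=len(internal))), dtype=np.int8
    )  # (3^k, k)
    col_of = {k: i for i, k in enumerate(internal)}

    def node_states(key):
        if key in leaf_labels:
            row = states_matrix[state_of_taxon[leaf_labels[key]]]
            return np.broadcast_to(row, (len(assigns), nchar))
        return np.broadcast_to(
            assigns[:, col_of[key]][:, None], (len(assigns), nchar)
        )

    changes = np.zeros((len(assigns), nchar), dtype=np.int32)
    for a, b in edges:
        changes += node_states(a) != node_states(b)
    return int(changes.min(axis=0).sum())


def brute_force_likelihood(tree, taxa, states_matrix, p_of):
    """Likelihood by summing over all internal-node state assignments.

    ``p_of(b)`` returns the 3x3 transition matrix for branch length b.
    Root prior uniform 1/3.  Returns the log-likelihood summed over
    characters.
    """
    edges = []
    keys = {}
    lengths = {}
    leaf_labels = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[node] = i
        if node.is_leaf():
            leaf_labels[i] = node.taxon.label
        if node.parent_node is not None:
            edges.append((keys[node.parent_node], i))
            lengths[(keys[node.parent_node], i)] = node.edge.length or 0.0
    root_key = 0
    all_keys = sorted({k for e in edges for k in e} | {root_key})
    internal = [k for k in all_keys if k not in leaf_labels]
    state_of_taxon = {t: i for i, t in enumerate(taxa)}
    pmats = {e: p_of(lengths[e]) for e in edges}
    total = 0.0
    for c in range(states_matrix.shape[1]):
        leaf_state = {
            k: int(states_matrix[state_of_taxon[lab], c])
            for k, lab in leaf_labels.items()
        }
        lik = 0.0
        for assign in itertools.product((0, 1, 2), repeat=len(internal)):
            st = dict(zip(internal, assign))
            st.update(leaf_state)
            term = 1.0 / 3.0
            for e in edges:
                term *= pmats[e][st[e[0]], st[e[1]]]
            lik += term
        total += np.log(lik)
    return total


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def bh_qvalues(p):
    """Benjamini-Hochberg step-up: sort, p*m/rank, reverse cumulative min."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_tail(overlap, set_size, query_size, universe_size):
    """P(X >= overlap) by direct summation of combination counts."""
    denom = comb(universe_size, query_size)
    total = 0
    for k in range(overlap, min(set_size, query_size) + 1):
        total += comb(set_size, k) * comb(universe_size - set_size, query_size - k)
    return total / denom


def informative_count_histogram(states):
    """Per-character informative flag via explicit state histograms."""
    n = 0
    for c in range(states.shape[1]):
        col = states[:, c]
        hist = [(col == s).sum() for s in (0, 1, 2)]
        if sum(1 for h in hist if h >= 2) >= 2:
            n += 1
    return n


def naive_nj(ids, d):
    """Textbook O(n^3)-per-step Neighbor Joining with dict bookkeeping.

    Returns (splits, sorted edge lengths): the non-trivial bipartitions
    (frozensets of the side not containing the smallest id) and the sorted
    list of all 2n-3 branch lengths, with the same tie-break (smallest
    index pair) and negative-length clamping rule as the specification.
    """
    n = len(ids)
    clusters = {i: frozenset([ids[i]]) for i in range(n)}
    dist = {(i, j): float(d[i][j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n
    merges = []
    lengths = []
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            q = (m - 2) * dist[(i, j)] - r[i] - r[j]
            if best is None or (q, i, j) < best:
                best = (q, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lengths += [li, max(lj, 0.0)]
        u = next_id
        next_id += 1
        clusters[u] = clusters[i] | clusters[j]
        merges.append(clusters[u])
        for k in active:
            if k not in (i, j):
                duk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dij)
                dist[(u, k)] = dist[(k, u)] = duk
        dist[(u, u)] = 0.0
        active = [a for a in active if a not in (i, j)] + [u]
    i, j = active
    lengths.append(max(dist[(i, j)], 0.0))
    all_set = frozenset(ids)
    ref = min(all_set)
    out_splits = set()
    for s in merges:
        side = all_set - s if ref in s else s
        if 1 < len(side) < len(all_set) - 1:
            out_splits.add(side)
    return out_splits, sorted(lengths)
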