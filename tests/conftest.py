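import dendropy
import numpy as np
import pandas as pd
import pytest

from exprphylo.discretize import CharacterMatrix, RatioMatrix
from exprphylo.io_formats import ExpressionMatrix, parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def worked_ratio_matrix():
    """2 genes x 4 taxa log-ratio matrix used for the threshold search."""
    values = pd.DataFrame(
        {
            "s1": [1.2, 0.2],
            "s2": [1.1, 0.3],
            "s3": [-1.3, -0.2],
            "s4": [-1.2, -0.3],
        },
        index=["g1", "g2"],
    )
    return RatioMatrix(values=values, outgroup_id="outgroup_t0")


@pytest.fixture
def quartet_cm():
    """Single character with the AB|CD pattern."""
    return CharacterMatrix(taxa=list("ABCD"), states=np.array([[2], [2], [0], [0]]))


def random_character_matrix(rng, n_taxa, n_chars, labels=None):
    taxa = labels or [f"T{i}" for i in range(n_taxa)]
    states = rng.integers(0, 3, size=(n_taxa, n_chars)).astype(np.int8)
    return CharacterMatrix(taxa=taxa, states=states)


def random_tree_with_lengths(rng, labels, min_len=0.1, max_len=2.0):
    """Random binary unrooted topology with uniform positive branch lengths."""
    from exprphylo import _tree

    n = len(labels)
    root = _tree._base_tree()
    for k in range(3, n):  # random stepwise addition
        pts = _tree._insertion_points(root)
        c = pts[rng.integers(0, len(pts))]
        _tree._insert_above(c, _tree.SNode(taxon=k))
    tree = _tree.snode_to_dendropy(root, list(labels), unroot=True)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(min_len, max_len))
    return tree


def expression_from_array(arr, sample_ids=None, time_rank=None, outgroup_rank=None):
    arr = np.asarray(arr, dtype=float)
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    genes = [f"g{i}" for i in range(arr.shape[0])]
    meta = pd.DataFrame(
        {
            "time_rank": time_rank if time_rank is not None else list(range(arr.shape[1])),
            "replicate": ["r1"] * arr.shape[1],
            "is_outgroup": [False] * arr.shape[1],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if outgroup_rank is not None:
        meta["is_outgroup"] = meta["time_rank"] == outgroup_rank
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=sample_ids), meta)
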