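"""Major-clade extraction, clade-differential genes, and set enrichment.

After rooting, the two children of the root define the tree's two major
clades (for a treatment time course: the "early" admixed clade and the
"late" resolved clade).  Genes separating the clades are found either by a
Welch t-test with Benjamini-Hochberg correction (default, replicates
permitting) or as synapomorphies of the discretized states.  Gene-set
enrichment uses the upper-tail hypergeometric test per set with a
permutation family-wise adjusted p: the fraction of random same-size
queries whose best (minimum) raw p beats the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _tree
from .discretize import CharacterMatrix
from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "CladeSplit",
    "split_major_clades",
    "differential_genes",
    "hypergeometric_p",
    "enrichment",
    "EnrichmentResult",
]


@dataclass
class CladeSplit:
    """The two leaf sets of the root bipartition plus the edge's support."""

    clade_a: frozenset
    clade_b: frozenset
    support: int | None = None

    @property
    def leaves(self) -> frozenset:
        return self.clade_a | self.clade_b


def split_major_clades(
    tree: dendropy.Tree,
    exclude_outgroup: bool = True,
    outgroup: set | None = None,
) -> CladeSplit:
    """Bipartition the rooted tree at its root.

    With ``exclude_outgroup`` the outgroup leaves (``outgroup`` labels, or
    the root child that is a single leaf / the smaller root clade when it
    is a pure outgroup attachment) are pruned first; the remaining root
    must then have exactly two children.
    """
    if not tree.is_rooted or len(tree.seed_node.child_nodes()) != 2:
        raise ValueError(
            "split_major_clades requires a rooted, bifurcating tree; "
            "root it on the outgroup first (root_at)"
        )
    work = tree.clone(depth=1)
    if exclude_outgroup and outgroup:
        keep = [
            lf.taxon for lf in work.leaf_node_iter() if lf.taxon.label not in outgroup
        ]
        if len(keep) < 4:
            raise ValueError("fewer than 4 leaves left after outgroup pruning")
        work.retain_taxa(keep)
        work.is_rooted = True
        # pruning can leave a degree-1 root; walk down to the first fork
        while len(work.seed_node.child_nodes()) == 1:
            child = work.seed_node.child_nodes()[0]
            work.seed_node = child
    children = work.seed_node.child_nodes()
    if len(children) != 2:
        raise ValueError(
            f"root has {len(children)} children after pruning; "
            "reroot the tree so its root is a bifurcation"
        )
    if len(_tree.leaf_labels(work)) < 4:
        raise ValueError("major-clade split needs >= 4 leaves")
    below = _tree._node_leafsets(work)
    a, b = (frozenset(below[c]) for c in children)
    support = None
    for c in children:
        if c.label is not None:
            try:
                support = int(c.label)
                break
            except ValueError:
                pass
    return CladeSplit(clade_a=a, clade_b=b, support=support)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up)."""
    return multipletests(p, method="fdr_bh")[1]


def differential_genes(
    expr: ExpressionMatrix,
    split: CladeSplit,
    mode: str = "welch_bh",
    alpha: float = 0.05,
    cm: CharacterMatrix | None = None,
) -> pd.DataFrame:
    """Genes that separate the two major clades.

    ``welch_bh``: per-gene unequal-variance two-sample t, two-sided p, BH q,
    ``significant`` iff q < alpha.  ``synapomorphy``: genes whose
    discretized state (from ``cm``) is uniform within each clade and
    differs between clades.  Returns a DataFrame indexed by gene.
    """
    a = [s for s in expr.sample_ids if s in split.clade_a]
    b = [s for s in expr.sample_ids if s in split.clade_b]
    if mode == "welch_bh":
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                "welch_bh needs >= 2 samples per clade; use mode='synapomorphy'"
            )
        xa = expr.values[a].to_numpy(dtype=float)
        xb = expr.values[b].to_numpy(dtype=float)
        with warnings.catch_warnings():
            # constant genes trigger a precision warning; they map to p=1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        t = np.nan_to_num(t, nan=0.0)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical gene
        q = bh_adjust(p)
        diff = xa.mean(axis=1) - xb.mean(axis=1)
        return pd.DataFrame(
            {
                "statistic": t,
                "p": p,
                "q": q,
                "direction": np.where(diff > 0, "up_in_a", np.where(diff < 0, "up_in_b", "none")),
                "significant": q < alpha,
                "mode": "welch_bh",
            },
            index=expr.values.index,
        )
    if mode == "synapomorphy":
        if cm is None:
            raise ValueError("synapomorphy mode needs the discretized CharacterMatrix")
        taxon_idx = {t: i for i, t in enumerate(cm.taxa)}
        ia = [taxon_idx[s] for s in a if s in taxon_idx]
        ib = [taxon_idx[s] for s in b if s in taxon_idx]
        sa, sb = cm.states[ia], cm.states[ib]
        uniform_a = (sa == sa[0]).all(axis=0)
        uniform_b = (sb == sb[0]).all(axis=0)
        hit = uniform_a & uniform_b & (sa[0] != sb[0])
        genes = cm.characters if cm.characters is not None else [
            f"c{i}" for i in range(cm.n_characters)
        ]
        return pd.DataFrame(
            {
                "state_a": sa[0],
                "state_b": sb[0],
                "significant": hit,
                "mode": "synapomorphy",
            },
            index=pd.Index(genes, name="gene"),
        )
    raise ValueError(f"unknown mode {mode!r}; options: welch_bh, synapomorphy")


def hypergeometric_p(
    overlap: int, set_size: int, query_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap)."""
    if not (0 <= overlap <= min(set_size, query_size)):
        raise ValueError("overlap must lie in [0, min(set_size, query_size)]")
    if max(set_size, query_size) > universe_size:
        raise ValueError("set and query must fit inside the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


@dataclass
class EnrichmentResult:
    """Per-set enrichment with permutation family-wise adjusted p."""

    table: pd.DataFrame
    n_permutations: int
    universe_size: int
    query_size: int
    seed: int | None = None


def enrichment(
    query,
    collection: GeneSetCollection,
    universe=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment with a min-p permutation adjustment.

    The adjusted p of a set is the fraction of ``n_perm`` random queries of
    the same size (drawn uniformly without replacement from the universe)
    whose minimum raw p over the whole collection is <= the set's observed
    raw p — the family-wise construction used by FuncAssociate.
    """
    query = list(dict.fromkeys(query))
    if not query:
        raise ValueError("query gene list is empty")
    if universe is None:
        universe = collection.universe
    if universe is None:
        raise ValueError("no universe: pass one or set it on the collection")
    universe = sorted(set(universe))
    missing = set(query) - set(universe)
    if missing:
        raise ValueError(f"query genes outside the universe: {sorted(missing)}")
    uidx = {g: i for i, g in enumerate(universe)}
    n_u = len(universe)
    n_q = len(query)
    names = collection.names
    # membership matrix over the universe
    member = np.zeros((len(names), n_u), dtype=np.float64)
    for si, name in enumerate(names):
        for g in collection.sets[name]:
            if g in uidx:
                member[si, uidx[g]] = 1.0
    set_sizes = member.sum(axis=1).astype(int)
    qvec = np.zeros(n_u)
    qvec[[uidx[g] for g in query]] = 1.0
    overlaps = (member @ qvec).astype(int)
    # precompute p as a function of overlap count per set
    pmax = int(min(n_q, set_sizes.max() if len(set_sizes) else 0))
    ks = np.arange(pmax + 2)
    p_by_k = np.stack(
        [stats.hypergeom.sf(ks - 1, n_u, m, n_q) for m in set_sizes]
    )  # n_sets x (pmax+2)
    raw_p = np.array([p_by_k[i, overlaps[i]] for i in range(len(names))])
    rng = np.random.default_rng(seed)
    min_ps = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.choice(n_u, size=n_q, replace=False)
        pv = np.zeros(n_u)
        pv[perm] = 1.0
        ov = (member @ pv).astype(int)
        min_ps[r] = min(p_by_k[i, ov[i]] for i in range(len(names)))
    adj = np.array([(min_ps <= p + 1e-15).mean() for p in raw_p])
    table = pd.DataFrame(
        {
            "set_size": set_sizes,
            "overlap": overlaps,
            "query_size": n_q,
            "universe_size": n_u,
            "p": raw_p,
            "adjusted_p": adj,
        },
        index=pd.Index(names, name="gene_set"),
    ).sort_values("p")
    return EnrichmentResult(
        table=table,
        n_permutations=n_perm,
        universe_size=n_u,
        query_size=n_q,
        seed=seed,
    )
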