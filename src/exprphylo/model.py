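"""Model-style front end: build once from data, fit, inspect results.

`ExpressionPhylogeny` wraps a longitudinal expression matrix (samples are
taxa, genes are characters) and `fit()` runs one of the three tree
reconstructions — Neighbor Joining on continuous distances, maximum
parsimony or maximum likelihood on 3-state discretized characters — with
optional bootstrap support, returning a `PhylogenyResults` that carries
the rooted tree, the threshold search, supports, fit statistics and entry
points to the downstream clade analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .clade_analysis import (
    CladeSplit,
    differential_genes,
    enrichment,
    split_major_clades,
)
from .discretize import (
    CharacterMatrix,
    ThresholdSearchResult,
    count_informative,
    discretize,
    log_ratio_matrix,
    select_threshold,
)
from .distance_trees import DistanceMatrix, compute_distance, neighbor_joining, root_at
from .io_formats import ExpressionMatrix, default_sample_meta
from .likelihood import ml_search
from .parsimony import parsimony_search
from .support_and_compare import SupportTree, bootstrap_support, temporal_order_score

__all__ = ["ExpressionPhylogeny", "PhylogenyResults"]


class ExpressionPhylogeny:
    """Phylogenetic clustering model over a gene x sample expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Expression with per-sample time ranks; one time point must be (or
        be designated as) the outgroup used for rooting and, for the
        discrete methods, as the up/down reference.
    outgroup_rank : int, optional
        Time rank to flag as outgroup when the matrix does not flag one.
    """

    def __init__(self, expr: ExpressionMatrix, outgroup_rank: int | None = None):
        if outgroup_rank is not None:
            expr = expr.with_outgroup(outgroup_rank)
        if not expr.outgroup_samples:
            raise ValueError(
                "no outgroup designated; pass outgroup_rank or flag sample_meta.is_outgroup"
            )
        self.expr = expr.ensure_log()

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        time_rank=None,
        replicate=None,
        outgroup_rank: int = 0,
        log_scale: bool = True,
    ) -> "ExpressionPhylogeny":
        """Build from a genes x samples DataFrame plus per-sample time ranks."""
        meta = default_sample_meta(list(values.columns))
        if time_rank is not None:
            meta["time_rank"] = [time_rank[s] for s in values.columns]
        if replicate is not None:
            meta["replicate"] = [replicate[s] for s in values.columns]
        expr = ExpressionMatrix(values, meta, log_scale=log_scale)
        return cls(expr, outgroup_rank=outgroup_rank)

    # ------------------------------------------------------------------
    def fit(
        self,
        method: str = "nj",
        metric: str = "euclidean",
        tau="auto",
        grid=None,
        strategy: str = "nni_from_nj",
        bootstrap: int = 0,
        seed: int | None = None,
    ) -> "PhylogenyResults":
        """Reconstruct the rooted tree by ``method`` (nj, parsimony, ml)."""
        expr = self.expr
        outgroup = expr.outgroup_samples
        dm = threshold = cm = None
        score = loglik = None
        ratio = None

        if method == "nj":
            dm = compute_distance(expr, metric=metric)
            unrooted = neighbor_joining(dm)
            root_on = outgroup if len(outgroup) > 1 else outgroup[0]
        elif method in ("parsimony", "ml"):
            ratio = log_ratio_matrix(expr)
            if tau == "auto":
                threshold = select_threshold(ratio, grid=grid)
                tau_val = threshold.selected_tau
            else:
                tau_val = float(tau)
            cm = discretize(ratio, tau_val)
            if method == "parsimony":
                res = parsimony_search(cm, strategy=strategy)
                unrooted, score = res.best_tree, res.score
            else:
                res = ml_search(cm, strategy=strategy)
                unrooted, loglik = res.best_tree, res.log_likelihood
            root_on = ratio.outgroup_id
        else:
            raise ValueError(f"unknown method {method!r}; options: nj, parsimony, ml")

        support = None
        if bootstrap:
            data = expr if method == "nj" else cm
            support = bootstrap_support(
                data,
                method=method,
                n_reps=bootstrap,
                seed=seed,
                metric=metric,
                strategy=strategy,
            )
            unrooted = support.tree
        try:
            rooted = root_at(unrooted, root_on)
        except ValueError:
            if isinstance(root_on, str):
                raise
            # outgroup replicates not monophyletic (noisy data): fall back
            # to rooting on the first outgroup leaf alone
            rooted = root_at(unrooted, root_on[0])
        return PhylogenyResults(
            model=self,
            method=method,
            tree=rooted,
            unrooted_tree=unrooted,
            distance_matrix=dm,
            threshold=threshold,
            character_matrix=cm,
            parsimony_score=score,
            log_likelihood=loglik,
            support=support,
            metric=metric if method == "nj" else None,
            outgroup=list(outgroup),
            outgroup_taxon=root_on if isinstance(root_on, str) else None,
        )


@dataclass
class PhylogenyResults:
    """Fitted expression phylogeny with diagnostics and clade analyses."""

    model: ExpressionPhylogeny
    method: str
    tree: dendropy.Tree
    unrooted_tree: dendropy.Tree
    distance_matrix: DistanceMatrix | None = None
    threshold: ThresholdSearchResult | None = None
    character_matrix: CharacterMatrix | None = None
    parsimony_score: int | None = None
    log_likelihood: float | None = None
    support: SupportTree | None = None
    metric: str | None = None
    outgroup: list = field(default_factory=list)
    outgroup_taxon: str | None = None

    # ------------------------------------------------------------------
    def newick(self) -> str:
        from .io_formats import tree_to_newick

        return tree_to_newick(self.tree)

    def temporal_order_score(self) -> float:
        """How well the rooted tree peels leaves off in time order (tau-b)."""
        meta = self.model.expr.sample_meta
        ranks = {s: int(meta.loc[s, "time_rank"]) for s in meta.index}
        if self.outgroup_taxon is not None and self.outgroup_taxon in (
            lf.taxon.label for lf in self.tree.leaf_node_iter()
        ):
            og_rank = int(meta.loc[self.outgroup[0], "time_rank"]) if self.outgroup else 0
            ranks[self.outgroup_taxon] = og_rank
        present = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        return temporal_order_score(self.tree, {k: v for k, v in ranks.items() if k in present})

    def major_clades(self, exclude_outgroup: bool = True) -> CladeSplit:
        og = set(self.outgroup)
        if self.outgroup_taxon:
            og.add(self.outgroup_taxon)
        return split_major_clades(
            self.tree, exclude_outgroup=exclude_outgroup, outgroup=og
        )

    def differential_genes(
        self, mode: str = "welch_bh", alpha: float = 0.05
    ) -> pd.DataFrame:
        split = self.major_clades()
        return differential_genes(
            self.model.expr, split, mode=mode, alpha=alpha, cm=self.character_matrix
        )

    def enrichment(self, collection, alpha: float = 0.05, n_perm: int = 1000,
                   seed: int | None = None):
        """Enrichment of the clade-differential genes against a collection."""
        table = self.differential_genes()
        query = list(table.index[table["significant"]])
        universe = list(self.model.expr.gene_ids)
        return enrichment(query, collection, universe=universe, n_perm=n_perm, seed=seed)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        expr = self.model.expr
        lines = []
        w = 58
        lines.append(" Expression Phylogeny Results ".center(w, "="))
        pairs = [
            ("Method:", self.method),
            ("No. taxa (samples):", expr.n_samples),
            ("No. characters (genes):", expr.n_genes),
            ("Outgroup:", ", ".join(self.outgroup) or "-"),
        ]
        if self.metric:
            pairs.append(("Distance metric:", self.metric))
        if self.threshold is not None:
            pairs.append(("Selected tau:", f"{self.threshold.selected_tau:.4f}"))
            pairs.append(("Informative sites:", self.threshold.selected_count))
        elif self.character_matrix is not None and self.character_matrix.n_taxa >= 4:
            pairs.append(("Tau:", f"{self.character_matrix.tau:.4f}"))
            pairs.append(("Informative sites:", count_informative(self.character_matrix)))
        if self.parsimony_score is not None:
            pairs.append(("Parsimony score:", self.parsimony_score))
        if self.log_likelihood is not None:
            pairs.append(("Log-likelihood:", f"{self.log_likelihood:.4f}"))
        if self.support is not None:
            vals = sorted(self.support.supports.values())
            if vals:
                pairs.append(
                    ("Bootstrap support:",
                     f"n={self.support.n_reps}, median={int(np.median(vals))}%")
                )
        try:
            pairs.append(("Temporal order score:", f"{self.temporal_order_score():.3f}"))
        except (ValueError, KeyError):
            pass
        for k, v in pairs:
            lines.append(f"{k:<28}{v}")
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PhylogenyResults method={self.method!r} "
            f"taxa={self.model.expr.n_samples}>"
        )
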