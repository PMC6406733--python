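"""Three-state discretization of expression relative to an outgroup.

Continuous log2 expression is converted into per-gene character states
{0 = downregulated, 1 = constant, 2 = upregulated} relative to the mean of
the outgroup (reference time point) replicates.  The up/down cut-off tau is
chosen by maximizing the number of parsimony-informative characters over a
grid, because parsimony reliability grows with the number of informative
characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "RatioMatrix",
    "CharacterMatrix",
    "ThresholdSearchResult",
    "log_ratio_matrix",
    "discretize",
    "count_informative",
    "informative_mask",
    "select_threshold",
    "default_tau_grid",
]


@dataclass
class RatioMatrix:
    """Genes x (non-outgroup) samples of log2 ratios versus the outgroup mean."""

    values: pd.DataFrame  # genes x samples
    outgroup_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("ratio matrix contains non-finite entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CharacterMatrix:
    """Taxa x characters over the 3-state alphabet {0: down, 1: constant, 2: up}."""

    taxa: list[str]
    states: np.ndarray  # (n_taxa, n_characters) int8
    characters: list[str] | None = None
    tau: float | None = None
    informative_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D taxa x characters array")
        if len(self.taxa) != self.states.shape[0]:
            raise ValueError("taxa list does not match state-matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.states.size and not np.isin(self.states, (0, 1, 2)).all():
            raise ValueError("states must be coded 0/1/2")
        if self.characters is not None and len(self.characters) != self.states.shape[1]:
            raise ValueError("character labels do not match state-matrix columns")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]


def log_ratio_matrix(expr: ExpressionMatrix, outgroup=None) -> RatioMatrix:
    """log2 ratios of every non-outgroup sample against the outgroup mean.

    ``outgroup`` may be omitted when the matrix already flags outgroup
    samples; otherwise it is a time rank whose samples become the reference.
    """
    expr = expr.ensure_log()
    if outgroup is not None:
        expr = expr.with_outgroup(outgroup)
    og = expr.outgroup_samples
    if not og:
        raise ValueError(
            "no outgroup designated; flag a reference time point "
            "(ExpressionMatrix.with_outgroup or sample_meta.is_outgroup)"
        )
    ref = expr.values[og].mean(axis=1)
    rest = [s for s in expr.sample_ids if s not in og]
    ratios = expr.values[rest].sub(ref, axis=0)
    rank = expr.sample_meta.loc[og, "time_rank"].iloc[0]
    return RatioMatrix(values=ratios, outgroup_id=f"outgroup_t{rank}")


def discretize(ratio: RatioMatrix, tau: float, include_outgroup: bool = True) -> CharacterMatrix:
    """Threshold log ratios into 3 states: >= tau up, <= -tau down, else constant.

    The outgroup itself, being the reference, is appended as an all-constant
    taxon when ``include_outgroup`` so trees can later be rooted on it.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    r = ratio.values.to_numpy(dtype=float)
    states = np.ones(r.shape, dtype=np.int8)
    states[r >= tau] = 2
    states[r <= -tau] = 0
    states = states.T  # taxa x characters
    taxa = list(ratio.sample_ids)
    if include_outgroup:
        taxa = taxa + [ratio.outgroup_id]
        states = np.vstack([states, np.ones((1, states.shape[1]), dtype=np.int8)])
    cm = CharacterMatrix(
        taxa=taxa, states=states, characters=list(ratio.gene_ids), tau=float(tau)
    )
    cm.informative_mask = informative_mask(cm.states)
    return cm


def informative_mask(states: np.ndarray) -> np.ndarray:
    """Boolean mask of parsimony-informative characters.

    A character is informative iff at least two distinct states each occur
    in at least two taxa.
    """
    states = np.asarray(states)
    counts = np.stack([(states == s).sum(axis=0) for s in (0, 1, 2)])  # 3 x nchar
    return (counts >= 2).sum(axis=0) >= 2


def count_informative(cm: CharacterMatrix) -> int:
    """Number of parsimony-informative characters in the matrix."""
    if cm.n_taxa < 4:
        raise ValueError(
            "parsimony-informative sites require >= 4 taxa "
            f"(got {cm.n_taxa}); no character can be informative"
        )
    return int(informative_mask(cm.states).sum())


def default_tau_grid(ratio: RatioMatrix, n: int = 21) -> np.ndarray:
    """21 evenly spaced thresholds between the 50th and 99th percentile of |ratio|."""
    a = np.abs(ratio.values.to_numpy(dtype=float)).ravel()
    lo, hi = np.percentile(a, [50, 99])
    lo = max(lo, 1e-9)
    hi = max(hi, lo * (1 + 1e-9))
    return np.linspace(lo, hi, n)


@dataclass
class ThresholdSearchResult:
    """Grid of candidate taus, informative counts, and the selected maximizer."""

    grid: np.ndarray
    counts: np.ndarray
    selected_tau: float
    include_outgroup: bool = True

    @property
    def selected_count(self) -> int:
        return int(self.counts[int(np.argmin(np.abs(self.grid - self.selected_tau)))])

    def as_dict(self) -> dict:
        return {
            "grid": [float(t) for t in self.grid],
            "informative_counts": [int(c) for c in self.counts],
            "selected_tau": float(self.selected_tau),
            "selected_count": self.selected_count,
            "outgroup_included_in_count": self.include_outgroup,
        }


def select_threshold(
    ratio: RatioMatrix,
    grid=None,
    include_outgroup: bool = True,
) -> ThresholdSearchResult:
    """Pick the tau maximizing the informative-site count over a grid.

    The objective is not monotone in tau, so the whole grid is evaluated;
    ties resolve to the smallest tau.  ``include_outgroup`` controls whether
    the all-constant outgroup taxon takes part in the count.
    """
    if grid is None:
        grid = default_tau_grid(ratio)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty tau grid")
    if (grid <= 0).any():
        raise ValueError("all grid taus must be positive")
    grid = np.sort(grid)
    counts = np.empty(grid.size, dtype=int)
    for i, tau in enumerate(grid):
        cm = discretize(ratio, tau, include_outgroup=include_outgroup)
        counts[i] = count_informative(cm)
    best = int(np.argmax(counts))  # argmax returns first (= smallest tau) on ties
    return ThresholdSearchResult(
        grid=grid,
        counts=counts,
        selected_tau=float(grid[best]),
        include_outgroup=include_outgroup,
    )
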