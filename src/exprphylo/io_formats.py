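"""Readers and writers for the formats the toolkit touches.

Expression tables (plain TSV or GEO series-matrix dialect), Newick trees,
discretized character matrices (relaxed PHYLIP / NEXUS), GMT gene-set
collections and long-format drug-screen plate tables.  Every reader
validates the invariants of the in-memory type it produces; every
writer/reader pair round-trips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ScreenDataset",
    "read_expression_table",
    "read_newick",
    "write_newick",
    "parse_newick",
    "tree_to_newick",
    "write_character_matrix",
    "read_character_matrix",
    "read_gmt",
    "read_plate_table",
    "collapse_probes",
]

GEO_TABLE_BEGIN = "!series_matrix_table_begin"
GEO_TABLE_END = "!series_matrix_table_end"

#: allowed categorical values on screen tables
CONTROL_KINDS = ("empty", "DMSO", "no_drug")
TREATMENTS = ("vehicle", "tgfb")
KNOCKDOWNS = ("siCtrl", "siATG16L1", "none")
DENSITIES = ("low", "high")

PLATE_COLUMNS = [
    "plate_id",
    "well_row",
    "well_col",
    "drug_id",
    "control_kind",
    "treatment",
    "knockdown",
    "density",
    "signal",
]


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are gene (or probe) ids, columns are sample ids.
    sample_meta : pandas.DataFrame
        Indexed by sample id with columns ``time_rank`` (non-negative int),
        ``replicate`` (str) and ``is_outgroup`` (bool).  At most one time
        point (all of its replicates) may be flagged as the outgroup.
    log_scale : bool
        Whether ``values`` are already on a log2 scale.  Discretization
        requires log scale; :meth:`ensure_log` converts linear data with
        ``log2(x + 1)``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    log_scale: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        meta = self.sample_meta
        required = {"time_rank", "replicate", "is_outgroup"}
        if not required.issubset(meta.columns):
            raise ValueError(
                f"sample_meta missing columns: {sorted(required - set(meta.columns))}"
            )
        if set(meta.index) != set(v.columns):
            raise ValueError("sample_meta index does not match sample ids")
        # align meta to column order
        self.sample_meta = meta.loc[v.columns]
        self.sample_meta.index.name = "sample_id"
        if (self.sample_meta["time_rank"] < 0).any():
            raise ValueError("time_rank must be non-negative")
        og = self.sample_meta[self.sample_meta["is_outgroup"]]
        if len(og) and og["time_rank"].nunique() != 1:
            raise ValueError("outgroup samples must all share one time point")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError(
                "expression values contain NaN/inf; impute or clean before use"
            )

    # -- convenience accessors ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def outgroup_samples(self) -> list[str]:
        m = self.sample_meta
        return list(m.index[m["is_outgroup"]])

    def ensure_log(self) -> "ExpressionMatrix":
        """Return self if already log-scale, else a log2(x+1) transformed copy."""
        if self.log_scale:
            return self
        vals = self.values.clip(lower=0.0)
        return ExpressionMatrix(np.log2(vals + 1.0), self.sample_meta.copy(), True)

    def with_outgroup(self, time_rank: int) -> "ExpressionMatrix":
        """Return a copy with the samples at ``time_rank`` flagged as outgroup."""
        meta = self.sample_meta.copy()
        if not (meta["time_rank"] == time_rank).any():
            raise ValueError(f"no samples at time_rank {time_rank}")
        meta["is_outgroup"] = meta["time_rank"] == time_rank
        return ExpressionMatrix(self.values, meta, self.log_scale)


def default_sample_meta(sample_ids: list[str]) -> pd.DataFrame:
    """Metadata placeholder: rank equals column order, no outgroup."""
    return pd.DataFrame(
        {
            "time_rank": np.arange(len(sample_ids)),
            "replicate": ["r1"] * len(sample_ids),
            "is_outgroup": [False] * len(sample_ids),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _to_numeric_strict(df: pd.DataFrame) -> pd.DataFrame:
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return num


def _read_geo_block(text: str) -> pd.DataFrame:
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip() == GEO_TABLE_BEGIN)
        end = next(i for i, l in enumerate(lines) if l.strip() == GEO_TABLE_END)
    except StopIteration:
        raise ValueError(
            "GEO series-matrix table markers not found "
            f"({GEO_TABLE_BEGIN!r} / {GEO_TABLE_END!r})"
        ) from None
    block = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(io.StringIO(block), sep="\t", index_col=0, dtype=str)
    # GEO quotes ids; strip quotes from index and header
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def read_expression_table(
    path,
    dialect: str = "tsv",
    meta=None,
    log_scale: bool = True,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a gene x sample expression table.

    ``dialect`` is ``"tsv"`` (header row of sample ids, first column gene
    ids) or ``"geo_series_matrix"`` (the data block between the standard
    begin/end table markers).  ``meta`` may be a DataFrame or a path to a
    TSV with columns sample_id, time_rank, replicate, is_outgroup; absent
    metadata defaults to column order with no outgroup.  ``impute_missing``
    replaces NaN cells by the per-gene median instead of rejecting them.
    """
    with open(path) as fh:
        text = fh.read()
    if dialect == "tsv":
        raw = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    elif dialect == "geo_series_matrix":
        raw = _read_geo_block(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; options: tsv, geo_series_matrix")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup}")
    values = _to_numeric_strict(raw)
    if impute_missing:
        med = values.median(axis=1)
        values = values.apply(lambda col: col.fillna(med))
    if meta is None:
        meta_df = default_sample_meta(list(values.columns))
    elif isinstance(meta, pd.DataFrame):
        meta_df = meta
    else:
        meta_df = pd.read_csv(meta, sep="\t").set_index("sample_id")
        meta_df["is_outgroup"] = meta_df["is_outgroup"].astype(bool)
    return ExpressionMatrix(values, meta_df, log_scale=log_scale)


def collapse_probes(expr: ExpressionMatrix, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse probe rows to gene symbols keeping, per gene, the probe with
    the highest mean expression (max-mean collapse).  Probes without a
    mapping are dropped."""
    keep = expr.values.index.to_series().map(probe_to_gene).dropna()
    sub = expr.values.loc[keep.index]
    means = sub.mean(axis=1)
    best = (
        pd.DataFrame({"gene": keep.values, "mean": means.values}, index=sub.index)
        .sort_values("mean", ascending=False)
        .drop_duplicates("gene")
    )
    out = sub.loc[best.index]
    out.index = best["gene"].values
    return ExpressionMatrix(out, expr.sample_meta.copy(), expr.log_scale)


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(newick: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree.

    Internal node labels (bootstrap supports) are kept as node labels.
    Malformed input raises ValueError carrying the parser's location info.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises its own error hierarchy
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in Newick input")
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip()


def read_newick(path, rooted: bool | None = None) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Character matrices (relaxed PHYLIP / NEXUS over symbols 0/1/2)
# ---------------------------------------------------------------------------

def write_character_matrix(cm, path, format: str = "phylip_relaxed") -> None:
    """Serialize a 3-state character matrix.

    ``phylip_relaxed``: header line "ntaxa nchar", then "name<ws>states".
    ``nexus``: a DATA block with FORMAT SYMBOLS="012".
    """
    states = np.asarray(cm.states)
    if states.size == 0:
        raise ValueError("empty character matrix")
    if not np.isin(states, (0, 1, 2)).all():
        raise ValueError("character states must be coded 0/1/2")
    ntax, nchar = states.shape
    rows = ["".join(str(int(s)) for s in states[i]) for i in range(ntax)]
    if format == "phylip_relaxed":
        lines = [f"{ntax} {nchar}"]
        lines += [f"{cm.taxa[i]}  {rows[i]}" for i in range(ntax)]
    elif format == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={ntax} NCHAR={nchar};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;',
            "    MATRIX",
        ]
        lines += [f"        {cm.taxa[i]}  {rows[i]}" for i in range(ntax)]
        lines += ["    ;", "END;"]
    else:
        raise ValueError(f"unknown format {format!r}; options: phylip_relaxed, nexus")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_character_matrix(path, format: str = "phylip_relaxed"):
    """Read a 0/1/2 character matrix written by :func:`write_character_matrix`."""
    from .discretize import CharacterMatrix  # local import: avoid cycle

    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    taxa: list[str] = []
    rows: list[list[int]] = []
    if format == "phylip_relaxed":
        header = lines[0].split()
        ntax, nchar = int(header[0]), int(header[1])
        for line in lines[1 : 1 + ntax]:
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append([int(c) for c in seq.strip()])
    elif format == "nexus":
        in_matrix = False
        for line in lines:
            s = line.strip()
            if s.upper() == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if s == ";":
                    break
                if not s:
                    continue
                name, seq = s.split(None, 1)
                taxa.append(name)
                rows.append([int(c) for c in seq.strip()])
        nchar = len(rows[0]) if rows else 0
    else:
        raise ValueError(f"unknown format {format!r}")
    states = np.asarray(rows, dtype=np.int8)
    if states.ndim != 2 or any(len(r) != nchar for r in rows):
        raise ValueError("taxa with unequal character counts")
    return CharacterMatrix(taxa=taxa, states=states)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit universe."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {ln}: need name, description and >=1 gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            if not genes:
                raise ValueError(f"GMT line {ln}: set {name!r} has no genes")
            sets[name] = frozenset(genes)
            descs[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descs)


# ---------------------------------------------------------------------------
# Drug-screen plate tables
# ---------------------------------------------------------------------------

@dataclass
class ScreenDataset:
    """Well-level viability records of a drug screen.

    One row per well: plate_id, well_row, well_col, drug_id (empty for
    control wells), control_kind (empty/DMSO/no_drug for controls),
    treatment (vehicle/tgfb), knockdown (siCtrl/siATG16L1/none), density
    (low/high) and the viability ``signal`` (e.g. CellTiterGlo luminescence).
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate table missing required column(s): {missing}")
        key = df[["plate_id", "well_row", "well_col"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate well address {tuple(dup)}")
        if (df["signal"] < 0).any():
            raise ValueError("negative viability signal")
        for col, allowed in (
            ("treatment", TREATMENTS),
            ("knockdown", KNOCKDOWNS),
            ("density", DENSITIES),
        ):
            bad = set(df[col].dropna()) - set(allowed)
            if bad:
                raise ValueError(f"invalid {col} value(s): {sorted(bad)}")
        is_drug = df["drug_id"].notna() & (df["drug_id"] != "")
        bad_ctrl = set(df.loc[~is_drug, "control_kind"].dropna()) - set(CONTROL_KINDS)
        if bad_ctrl:
            raise ValueError(f"invalid control_kind value(s): {sorted(bad_ctrl)}")

    @property
    def drug_wells(self) -> pd.DataFrame:
        df = self.wells
        return df[df["drug_id"].notna() & (df["drug_id"] != "")]

    @property
    def control_wells(self) -> pd.DataFrame:
        df = self.wells
        return df[df["drug_id"].isna() | (df["drug_id"] == "")]

    @property
    def drugs(self) -> list[str]:
        return sorted(self.drug_wells["drug_id"].unique())


def read_plate_table(path) -> ScreenDataset:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing required column(s): {missing}")
    df["signal"] = pd.to_numeric(df["signal"])
    return ScreenDataset(df)


def write_plate_table(screen: ScreenDataset, path) -> None:
    screen.wells.to_csv(path, index=False)
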