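"""Readers and writers for the tabular artifacts of the essentiality pipeline.

All matrices are delimited text with genes as rows and a header row of
cell-line identifiers; tab and comma dialects are both accepted.  Gene
identifiers are uppercase official symbols throughout; no identifier mapping
is performed.  Missing values are allowed in matrices and propagate — every
statistical operation downstream drops them pairwise.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("logfc", "scaled", "probability")

ANNOTATION_COLUMNS = ("cell_line", "tissue", "cancer_type", "msi_status",
                      "growth_property")
MUTATION_COLUMNS = ("cell_line", "gene", "protein_change", "annotation_source")
CNV_COLUMNS = ("cell_line", "gene", "relative_copy_number")
DRUG_COLUMNS = ("cell_line", "drug_id", "response")

#: Edge-table schema.  "comparision_in" (sic) is the column spelling used in
#: the released network files this schema is compatible with.
EDGE_COLUMNS = ("source", "target", "project", "effector", "comparision_in",
                "higher", "median_group", "p_value", "correlation", "width",
                "dashes", "group_tier")


class FormatError(ValueError):
    """A file violated the expected tabular format."""


def _detect_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    if not sample:
        raise FormatError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


@dataclass
class ScreenMatrix:
    """Gene x cell-line numeric matrix.

    ``data`` holds one row per gene and one column per cell line; units are
    log2 fold changes (``logfc``), scaled essentiality scores (``scaled``) or
    essentiality probabilities (``probability``).
    """

    data: pd.DataFrame
    value_kind: str = "logfc"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("empty screen matrix")
        dup_genes = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_genes):
            raise FormatError(f"duplicate gene symbols: {sorted(dup_genes)}")
        dup_cells = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_cells):
            raise FormatError(f"duplicate cell-line IDs: {sorted(dup_cells)}")
        self.data = self.data.astype(float)
        if self.value_kind == "probability":
            vals = self.data.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("probability matrix has values outside [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="gene")


def read_screen_matrix(path: str | Path, value_kind: str = "logfc") -> ScreenMatrix:
    """Read a gene x cell-line matrix from delimited text.

    The delimiter is auto-detected among tab/comma.  Non-numeric cells become
    missing values.  Duplicate gene or cell-line identifiers are a hard error.
    """
    sep = _detect_delimiter(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    cells = header[1:]
    dup_cells = sorted({c for c in cells if cells.count(c) > 1})
    if dup_cells:
        raise FormatError(f"duplicate cell-line IDs: {dup_cells}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.upper()
    df = df.apply(pd.to_numeric, errors="coerce")
    return ScreenMatrix(df, value_kind)


def read_expression_matrix(path: str | Path) -> ScreenMatrix:
    """Read a log(FPKM + 1) expression matrix (all finite values must be >= 0)."""
    sm = read_screen_matrix(path, value_kind="logfc")
    vals = sm.data.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and finite.min() < 0:
        raise FormatError("expression matrix has negative values; expected log(FPKM + 1)")
    return sm


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one symbol per line, '#' comments allowed.

    Symbols are uppercased and deduplicated preserving first occurrence.
    """
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip().upper()
            if sym and sym not in seen:
                seen.add(sym)
                out.append(sym)
    if not out:
        raise FormatError(f"{path}: empty gene list")
    return out


@dataclass
class GeneSetCollection:
    """Mapping term_id -> (description, member gene symbols)."""

    descriptions: dict[str, str] = field(default_factory=dict)
    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.members.items():
            if not genes:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.members[term]

    def items(self):
        return self.members.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, members; tab-separated)."""
    descriptions: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            genes = [g.strip().upper() for g in fields[2:] if g.strip()]
            if len(fields) < 3 or not genes:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields "
                                  "(term, description, members)")
            descriptions[fields[0]] = fields[1]
            members[fields[0]] = frozenset(genes)
    if not members:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(descriptions, members)


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the cell-line annotation table (tissue, cancer type, MSI, growth)."""
    df = _read_table(path, ANNOTATION_COLUMNS)
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    dup = df["cell_line"][df["cell_line"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate cell-line IDs in annotations: {sorted(dup)}")
    # every cancer type must map to exactly one tissue
    mapping = df.groupby("cancer_type")["tissue"].nunique()
    bad = mapping[mapping > 1].index.tolist()
    if bad:
        raise FormatError(f"cancer types mapped to multiple tissues: {bad}")
    return df.reset_index(drop=True)


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, MUTATION_COLUMNS)
    df["gene"] = df["gene"].astype(str).str.upper()
    return df


def read_cnv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, CNV_COLUMNS)
    df["gene"] = df["gene"].astype(str).str.upper()
    if (df["relative_copy_number"] < 0).any():
        raise FormatError("negative relative copy numbers")
    return df


def read_drug_response(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, DRUG_COLUMNS)
    if not np.isfinite(df["response"]).all():
        raise FormatError("non-finite drug responses")
    return df


def read_node_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-gene boolean flags (is_TF, is_surfaceome, is_SLC, is_kinase)."""
    df = _read_table(path, ("gene",))
    df["gene"] = df["gene"].astype(str).str.upper()
    dup = df["gene"][df["gene"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate genes in node annotations: {sorted(dup)}")
    for col in df.columns:
        if col != "gene":
            df[col] = df[col].astype(bool)
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# Cell-line selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionFilters:
    """Filter slots for cell-line selection; every slot is optional.

    Within the mutation (resp. CNV) slot, genes combine according to
    ``mutation_combine`` / ``cnv_combine`` ("OR": at least one gene qualifies,
    "AND": all genes qualify).  The CNV range is inclusive on both ends.
    Slots combine as a conjunction.
    """

    mutated_genes: Sequence[str] | None = None
    mutation_combine: str = "OR"
    cnv_genes: Sequence[str] | None = None
    cnv_range: tuple[float, float] | None = None
    cnv_combine: str = "OR"
    tissues: Sequence[str] | None = None
    cancer_types: Sequence[str] | None = None
    msi_status: str | None = None
    growth_property: str | None = None


def _gene_slot_ids(table: pd.DataFrame, genes: Sequence[str], combine: str,
                   qualifies) -> set[str]:
    per_gene: list[set[str]] = []
    known = set(table["gene"].unique())
    for gene in genes:
        gene = gene.upper()
        if gene not in known:
            warnings.warn(f"gene {gene!r} not present in filter table; ignored",
                          stacklevel=3)
            continue
        sub = table[table["gene"] == gene]
        per_gene.append(set(sub.loc[qualifies(sub), "cell_line"]))
    if not per_gene:
        return set()
    if combine.upper() == "AND":
        return set.intersection(*per_gene)
    return set.union(*per_gene)


def select_cell_lines(annotations: pd.DataFrame,
                      mutations: pd.DataFrame | None = None,
                      cnv: pd.DataFrame | None = None,
                      filters: SelectionFilters | None = None) -> list[str]:
    """Return the sorted cell-line IDs satisfying every provided filter slot.

    Unknown genes in the mutation/CNV slots are ignored with a warning; an
    empty result is returned as an empty list, not an error.
    """
    filters = filters or SelectionFilters()
    ids = set(annotations["cell_line"])
    ann = annotations.set_index("cell_line")

    if filters.tissues is not None:
        ids &= set(ann.index[ann["tissue"].isin(filters.tissues)])
    if filters.cancer_types is not None:
        ids &= set(ann.index[ann["cancer_type"].isin(filters.cancer_types)])
    if filters.msi_status is not None:
        ids &= set(ann.index[ann["msi_status"] == filters.msi_status])
    if filters.growth_property is not None:
        ids &= set(ann.index[ann["growth_property"] == filters.growth_property])

    if filters.mutated_genes:
        if mutations is None:
            raise ValueError("mutation filter requires a mutation table")
        ids &= _gene_slot_ids(mutations, filters.mutated_genes,
                              filters.mutation_combine,
                              lambda sub: np.ones(len(sub), dtype=bool))
    if filters.cnv_genes:
        if cnv is None:
            raise ValueError("CNV filter requires a CNV table")
        lo, hi = filters.cnv_range if filters.cnv_range else (-np.inf, np.inf)
        ids &= _gene_slot_ids(cnv, filters.cnv_genes, filters.cnv_combine,
                              lambda sub: (sub["relative_copy_number"] >= lo)
                              & (sub["relative_copy_number"] <= hi))
    return sorted(ids)


# ---------------------------------------------------------------------------
# Network edge/node tables
# ---------------------------------------------------------------------------

def write_edge_table(graph, path: str | Path, sep: str = "\t") -> None:
    """Write a CEN graph as a TSV edge table (one row per edge)."""
    graph.to_frame().to_csv(path, sep=sep, index=False)


def read_edge_table(path: str | Path):
    """Read an edge table written by :func:`write_edge_table` back to a graph."""
    from .network import CENGraph  # local import to avoid a cycle

    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing edge columns {missing}")
    return CENGraph.from_frame(df)


def write_node_attributes(graph, path: str | Path,
                          annotations: pd.DataFrame | None = None,
                          sep: str = "\t") -> None:
    """Write a node table: gene, boolean annotation flags, degree."""
    rows = []
    for node in sorted(graph.nodes):
        row = {"gene": node, "degree": graph.degree(node)}
        if annotations is not None and node in annotations.index:
            row.update(annotations.loc[node].to_dict())
        elif annotations is not None:
            row.update({c: False for c in annotations.columns})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
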