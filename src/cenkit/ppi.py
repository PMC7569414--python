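"""Protein-protein interaction overlay and gene-set over-representation.

CEN node sets are mapped onto a STRING-dialect interaction network (edges
kept at combined score >= 400 by default) and tested for over-representation
in gene-set collections with the hypergeometric upper tail, adjusted across
terms with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import FormatError, GeneSetCollection, _detect_delimiter

DEFAULT_MIN_SCORE = 400
DEFAULT_FDR = 0.05

PPI_COLUMNS = ("protein1", "protein2", "combined_score")


def load_ppi(path, min_score: int = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Load a STRING-dialect edge list, keeping combined_score >= min_score.

    Edges are undirected: (a, b) and (b, a) are merged keeping the maximum
    score, and self-pairs are dropped.
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PPI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["protein1"] = df["protein1"].astype(str).str.upper()
    df["protein2"] = df["protein2"].astype(str).str.upper()
    df = df[df["protein1"] != df["protein2"]]
    a = df[["protein1", "protein2"]].min(axis=1)
    b = df[["protein1", "protein2"]].max(axis=1)
    canon = pd.DataFrame({"protein1": a, "protein2": b,
                          "combined_score": df["combined_score"].astype(int)})
    canon = (canon.groupby(["protein1", "protein2"], as_index=False)
             ["combined_score"].max())
    canon = canon[canon["combined_score"] >= min_score]
    return canon.sort_values(["protein1", "protein2"]).reset_index(drop=True)


def map_cen_to_ppi(cen_nodes: set[str], ppi: pd.DataFrame) -> nx.Graph:
    """Induced PPI subgraph on a CEN node set.

    Only edges with both endpoints in ``cen_nodes`` survive; query genes
    without interactions are retained as degree-0 nodes, so the output node
    set always equals the query set.
    """
    nodes = {g.upper() for g in cen_nodes}
    if not nodes:
        raise ValueError("empty node set")
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    sub = ppi[ppi["protein1"].isin(nodes) & ppi["protein2"].isin(nodes)]
    for _, row in sub.iterrows():
        g.add_edge(row["protein1"], row["protein2"],
                   combined_score=int(row["combined_score"]))
    return g


@dataclass
class EnrichmentResult:
    term_id: str
    description: str
    overlap_k: int
    set_size_K: int
    query_n: int
    background_N: int
    p_value: float
    fdr: float


def enrich(query: set[str], collection: GeneSetCollection,
           background: set[str], fdr_cutoff: float = DEFAULT_FDR,
           return_all: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Set members are intersected with ``background`` before testing; the
    p-value is the upper tail P(overlap >= observed); BH adjustment runs
    across all tested terms and results are filtered to fdr <= cutoff
    (unless ``return_all``) and sorted by p.
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background universe")

    N, n = len(background), len(query)
    rows = []
    for term, members in collection.items():
        in_bg = members & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(query & in_bg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, collection.descriptions.get(term, ""), k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term_id", "description", "overlap_k",
                                     "set_size_K", "query_n", "background_N",
                                     "p_value"])
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        return df
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    if not return_all:
        df = df[df["fdr"] <= fdr_cutoff].reset_index(drop=True)
    return df
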