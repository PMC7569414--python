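"""Context-specific essentiality networks (CENs).

A CEN is a typed, attribute-rich graph in which each edge records one
statistically significant association between a context (a tissue, a cancer
type, a mutated gene, an expressed gene, or another gene's essentiality
profile) and the essentiality of a target gene.  Edges carry the direction
of the effect, the median scaled essentiality of the test group, the p-value
or correlation, a 1-3 confidence level (``width``), a sample-size caution
flag (``dashes``, set for Group B associations), and the comparison scope.
Self-loops are allowed for a gene whose own expression correlates with its
own essentiality, and for a cancer driver whose own mutation raises its own
essentiality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import networkx as nx
import numpy as np
import pandas as pd

from .context import AssociationResult
from .io import EDGE_COLUMNS

logger = logging.getLogger(__name__)

EFFECTORS = ("tissue", "cancer", "expression", "hotspot_mutation",
             "oncogenic_mutation", "hotspot_co_mutation", "coessentiality")
#: effectors that may legitimately form self-loops
SELF_LOOP_EFFECTORS = ("expression", "hotspot_mutation")
CONTINUOUS_EFFECTORS = ("expression", "coessentiality")


@dataclass(frozen=True)
class ConfidenceBands:
    """Cut-offs mapping p-values / correlations to confidence levels 1-3.

    Discrete associations: level 1 for p in [0.01, 0.05), level 2 for
    p in [0.001, 0.01), level 3 for p < 0.001.  Continuous associations:
    level 1 for |r| in [0.4, 0.6) with p < 0.05, level 2 for |r| in
    [0.6, 0.8), level 3 for |r| >= 0.8.  Associations outside every band
    yield no edge.
    """

    p_level1: float = 0.05
    p_level2: float = 0.01
    p_level3: float = 0.001
    r_level1: float = 0.4
    r_level2: float = 0.6
    r_level3: float = 0.8
    r_level1_max_p: float = 0.05


DEFAULT_BANDS = ConfidenceBands()


def assign_confidence(result: AssociationResult,
                      bands: ConfidenceBands = DEFAULT_BANDS) -> int | None:
    """Confidence level (edge width) for an association, or None for no edge."""
    if result.correlation is not None:
        r, p = abs(result.correlation), result.p_value
        if r >= bands.r_level3:
            return 3
        if r >= bands.r_level2:
            return 2
        if r >= bands.r_level1 and p < bands.r_level1_max_p:
            return 1
        return None
    p = result.p_value
    if p < bands.p_level3:
        return 3
    if p < bands.p_level2:
        return 2
    if p < bands.p_level1:
        return 1
    return None


@dataclass
class CENEdge:
    source: str
    target: str
    project: str
    effector: str
    comparision_in: str  # (sic) matches the released network-file schema
    higher: str | None
    median_group: float | None
    p_value: float
    correlation: float | None
    width: int
    dashes: bool
    group_tier: str

    def __post_init__(self) -> None:
        if self.effector not in EFFECTORS:
            raise ValueError(f"unknown effector {self.effector!r}")
        if self.width not in (1, 2, 3):
            raise ValueError("width must be 1, 2 or 3")
        if self.source == self.target and self.effector not in SELF_LOOP_EFFECTORS:
            raise ValueError(f"self-loop not allowed for effector {self.effector!r}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.source, self.target, self.effector, self.comparision_in)


class CENGraph:
    """A CEN: nodes are genes and context labels, edges are associations."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._edges: dict[tuple, CENEdge] = {}

    # -- construction -------------------------------------------------------
    def add_edge(self, edge: CENEdge) -> None:
        if edge.key in self._edges:
            raise ValueError(f"duplicate edge {edge.key}")
        self._edges[edge.key] = edge
        self._g.add_edge(edge.source, edge.target,
                         key=(edge.effector, edge.comparision_in))

    def set_node_flags(self, annotations: pd.DataFrame) -> None:
        """Attach boolean flags (is_TF, ...) from a node-annotation table."""
        for node in self._g.nodes:
            if node in annotations.index:
                self._g.nodes[node].update(annotations.loc[node].to_dict())

    # -- inspection ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> list[CENEdge]:
        return list(self._edges.values())

    def node_flags(self, node: str) -> dict:
        return dict(self._g.nodes[node])

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.successors(node)) | set(self._g.predecessors(node))

    def __len__(self) -> int:
        return len(self._edges)

    # -- (de)serialisation --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(e) for e in sorted(self._edges.values(),
                                          key=lambda e: e.key)]
        return pd.DataFrame(rows, columns=EDGE_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CENGraph":
        graph = cls()
        for _, row in df.iterrows():
            graph.add_edge(CENEdge(
                source=row["source"], target=row["target"],
                project=row["project"], effector=row["effector"],
                comparision_in=row["comparision_in"],
                higher=None if pd.isna(row["higher"]) else row["higher"],
                median_group=(None if pd.isna(row["median_group"])
                              else float(row["median_group"])),
                p_value=float(row["p_value"]),
                correlation=(None if pd.isna(row["correlation"])
                             else float(row["correlation"])),
                width=int(row["width"]),
                dashes=bool(row["dashes"]),
                group_tier=row["group_tier"]))
        return graph

    def to_graphml(self, path) -> None:
        g = nx.MultiDiGraph()
        for e in self._edges.values():
            attrs = {k: ("" if v is None else v) for k, v in asdict(e).items()}
            g.add_edge(e.source, e.target, **attrs)
        nx.write_graphml(g, path)


def _edge_from_result(result: AssociationResult, project: str,
                      bands: ConfidenceBands) -> CENEdge | None:
    width = assign_confidence(result, bands)
    if width is None:
        return None
    ctype = result.context.context_type
    source = result.context.source_node or result.context.name
    if ctype in ("hotspot_mutation", "oncogenic_mutation"):
        # mutated gene -> essential gene; a hotspot association of a driver
        # with itself is a self-loop, two-gene hotspot links are co-mutation
        if ctype == "hotspot_mutation" and source != result.gene:
            effector = "hotspot_co_mutation"
        else:
            effector = ctype
    elif ctype in ("tissue", "cancer", "expression", "coessentiality"):
        effector = ctype
    elif ctype == "msi":
        effector = "tissue"  # genome-stability contexts render as group edges
    else:
        logger.info("skipping result with unsupported context type %r", ctype)
        return None
    return CENEdge(
        source=source, target=result.gene, project=project, effector=effector,
        comparision_in=result.context.comparison_in, higher=result.higher,
        median_group=result.median_group, p_value=result.p_value,
        correlation=result.correlation, width=width,
        dashes=result.group_tier == "B", group_tier=result.group_tier)


def build_cen(results: list[AssociationResult],
              annotations: pd.DataFrame | None = None,
              project: str = "SYNTH",
              bands: ConfidenceBands = DEFAULT_BANDS) -> CENGraph:
    """Assemble surviving associations into a CEN.

    Associations below the lowest confidence band emit no edge; results
    missing required fields are skipped with a logged reason.
    """
    graph = CENGraph()
    for result in results:
        if result is None:
            continue
        try:
            edge = _edge_from_result(result, project, bands)
        except (ValueError, AttributeError) as exc:
            logger.info("skipping malformed result %r: %s", result, exc)
            continue
        if edge is not None:
            graph.add_edge(edge)
    if annotations is not None:
        graph.set_node_flags(annotations)
    return graph


@dataclass
class FilterCriteria:
    """Edge filters for CEN subsetting; unset slots do not constrain.

    ``min_median`` and ``min_width`` are either scalars or per-effector
    mappings.  Edges with an absent median_group pass median filters; edges
    with an absent ``higher`` pass direction filters.
    """

    min_median: float | dict[str, float] | None = None
    min_width: int | dict[str, int] | None = None
    effectors: set[str] | None = None
    directions: set[str] | None = None
    group_tiers: set[str] | None = None
    scope: str | None = None
    project: str | None = None
    correlation_sign: str | None = None   # "positive" | "negative"
    dashes: bool | None = None

    def _lookup(self, table, effector, default=None):
        if table is None:
            return default
        if isinstance(table, dict):
            return table.get(effector, default)
        return table

    def admits(self, edge: CENEdge) -> bool:
        if self.project is not None and edge.project != self.project:
            return False
        if self.scope is not None and edge.comparision_in != self.scope:
            return False
        if self.effectors is not None and edge.effector not in self.effectors:
            return False
        if self.group_tiers is not None and edge.group_tier not in self.group_tiers:
            return False
        if self.dashes is not None and edge.dashes != self.dashes:
            return False
        min_w = self._lookup(self.min_width, edge.effector)
        if min_w is not None and edge.width < min_w:
            return False
        min_m = self._lookup(self.min_median, edge.effector)
        if (min_m is not None and edge.median_group is not None
                and not edge.median_group > min_m):
            return False
        if (self.directions is not None and edge.higher is not None
                and edge.higher not in self.directions):
            return False
        if self.correlation_sign is not None and edge.correlation is not None:
            if self.correlation_sign == "positive" and edge.correlation < 0:
                return False
            if self.correlation_sign == "negative" and edge.correlation > 0:
                return False
        return True


#: recommended threshold presets for the median essentiality of the test group
LENIENT_MEDIAN = 0.2
MEDIUM_MEDIAN = 0.3
STRINGENT_MEDIAN = 0.4


def filter_cen(graph: CENGraph, criteria: FilterCriteria | None = None) -> CENGraph:
    """Subgraph of edges satisfying every provided criterion (may be empty)."""
    criteria = criteria or FilterCriteria()
    out = CENGraph()
    for edge in graph.edges:
        if criteria.admits(edge):
            out.add_edge(replace(edge))
    for node in out.nodes:
        if node in graph.nodes:
            out._g.nodes[node].update(graph.node_flags(node))
    return out


def extract_gene_cen(graph: CENGraph, gene: str, scope: str | None = None,
                     extra_genes: list[str] | None = None) -> CENGraph:
    """Induced subgraph on a gene, its neighbours and an optional extra list,
    optionally restricted to one comparison scope."""
    if gene not in graph.nodes:
        raise KeyError(f"gene {gene!r} not in graph")
    keep = {gene} | graph.neighbors(gene) | set(extra_genes or [])
    out = CENGraph()
    for edge in graph.edges:
        if edge.source in keep and edge.target in keep:
            if scope is not None and edge.comparision_in != scope:
                continue
            out.add_edge(replace(edge))
    return out
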