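import numpy as np
import pandas as pd
import pytest

from cenkit import (AssociationResult, CENEdge, CENGraph, ContextSpec,
                    FilterCriteria, assign_confidence, build_cen,
                    extract_gene_cen, filter_cen)


def _discrete_result(gene, p, context_type="tissue", source="Skin",
                     higher="high_in_group", median=0.7, n=(10, 30),
                     scope="Pancancer"):
    ctx = ContextSpec(kind="discrete", name=f"{context_type}:{source}",
                      context_type=context_type, source_node=source,
                      comparison_in=scope,
                      test_ids=tuple(f"t{i}" for i in range(n[0])),
                      control_ids=tuple(f"c{i}" for i in range(n[1])))
    from cenkit.context import group_tier
    return AssociationResult(gene=gene, context=ctx, statistic=1.0, p_value=p,
                             higher=higher, median_group=median,
                             n_test=n[0], n_control=n[1],
                             group_tier=group_tier(*n))


def _continuous_result(gene, r, p, source=None, scope="Pancancer"):
    source = source or gene
    ctx = ContextSpec(kind="continuous", name=f"expression:{source}",
                      context_type="expression", source_node=source,
                      comparison_in=scope, covariate={"c0": 1.0})
    return AssociationResult(gene=gene, context=ctx, statistic=r, p_value=p,
                             correlation=r, n_test=10, n_control=10,
                             group_tier="A")


@pytest.mark.parametrize("p,width", [
    (0.03, 1), (0.049999, 1), (0.005, 2), (0.0005, 3), (0.05, None), (0.2, None)])
def test_discrete_confidence_bands(p, width):
    assert assign_confidence(_discrete_result("G", p)) == width


@pytest.mark.parametrize("r,p,width", [
    (0.65, 0.005, 2), (0.45, 0.01, 1), (0.45, 0.2, None),
    (0.85, 0.0001, 3), (-0.85, 0.0001, 3), (0.3, 0.001, None)])
def test_continuous_confidence_bands(r, p, width):
    assert assign_confidence(_continuous_result("G", r, p)) == width


def test_expression_self_loop_has_width_three():
    graph = build_cen([_continuous_result("SOX10", 0.85, 1e-4)])
    assert len(graph) == 1
    edge = graph.edges[0]
    assert edge.source == edge.target == "SOX10"
    assert edge.effector == "expression" and edge.width == 3


def test_empty_results_build_an_empty_graph():
    assert len(build_cen([])) == 0


def test_insignificant_results_emit_no_edges():
    results = [
        _discrete_result("G1", 0.02),
        _discrete_result("G2", 0.004),
        _continuous_result("G3", 0.7, 0.001),
        _discrete_result("G4", 0.2),          # below band 1
        _continuous_result("G5", 0.2, 0.5),   # |r| too small
    ]
    graph = build_cen(results)
    assert len(graph) == 3
    assert {e.target for e in graph.edges} == {"G1", "G2", "G3"}


def test_mutation_effector_split_self_vs_co_mutation():
    own = _discrete_result("BRAF", 0.001, context_type="hotspot_mutation",
                           source="BRAF")
    other = _discrete_result("MAPK1", 0.001, context_type="hotspot_mutation",
                             source="BRAF")
    graph = build_cen([own, other])
    by_target = {e.target: e for e in graph.edges}
    assert by_target["BRAF"].effector == "hotspot_mutation"
    assert by_target["BRAF"].source == by_target["BRAF"].target
    assert by_target["MAPK1"].effector == "hotspot_co_mutation"


def test_self_loop_forbidden_for_group_effectors():
    with pytest.raises(ValueError, match="self-loop"):
        CENEdge(source="Skin", target="Skin", project="P", effector="tissue",
                comparision_in="Pancancer", higher=None, median_group=None,
                p_value=0.01, correlation=None, width=1, dashes=False,
                group_tier="A")


def test_group_b_edges_are_dashed():
    res = _discrete_result("G1", 0.002, n=(4, 30))
    graph = build_cen([res])
    assert graph.edges[0].dashes is True
    assert graph.edges[0].group_tier == "B"


def test_width_is_consistent_with_reassigning_confidence():
    results = [_discrete_result(f"G{i}", p) for i, p in
               enumerate([0.03, 0.004, 0.0002])]
    results += [_continuous_result("E1", 0.7, 0.001)]
    graph = build_cen(results)
    for edge in graph.edges:
        replayed = (_continuous_result("x", edge.correlation, edge.p_value)
                    if edge.correlation is not None
                    else _discrete_result("x", edge.p_value))
        assert assign_confidence(replayed) == edge.width


def test_median_threshold_drops_low_median_mutation_edge():
    keep = _discrete_result("G1", 0.001, context_type="hotspot_mutation",
                            source="M1", median=0.55)
    drop = _discrete_result("G2", 0.001, context_type="hotspot_mutation",
                            source="M2", median=0.35)
    graph = build_cen([keep, drop])
    out = filter_cen(graph, FilterCriteria(
        min_median={"hotspot_mutation": 0.4, "hotspot_co_mutation": 0.4}))
    assert {e.target for e in out.edges} == {"G1"}


def test_empty_criteria_is_identity():
    graph = build_cen([_discrete_result("G1", 0.01),
                       _continuous_result("G2", 0.9, 1e-5)])
    out = filter_cen(graph, FilterCriteria())
    pd.testing.assert_frame_equal(out.to_frame(), graph.to_frame())


def _protocol_fixture():
    """Eight edges of which exactly four satisfy the co-essential CEN
    protocol clauses (project, scope, effector set, direction-or-absent,
    positive-or-absent median, width >= 2, not dashed)."""
    def edge(i, **kw):
        base = dict(source=f"S{i}", target=f"T{i}", project="BROAD",
                    effector="tissue", comparision_in="Skin",
                    higher="high_in_group", median_group=0.5, p_value=0.001,
                    correlation=None, width=2, dashes=False, group_tier="A")
        base.update(kw)
        return CENEdge(**base)

    passing = [
        edge(0),
        edge(1, effector="expression", higher=None, correlation=0.9, width=3),
        edge(2, effector="hotspot_mutation", source="T2"),
        edge(3, effector="hotspot_co_mutation", width=3),
    ]
    failing = [
        edge(4, width=1),                               # confidence too low
        edge(5, dashes=True, group_tier="B"),           # Group B caution flag
        edge(6, effector="coessentiality", correlation=0.9),  # wrong effector
        edge(7, higher="low_in_group"),                 # wrong direction
    ]
    g = CENGraph()
    for e in passing + failing:
        g.add_edge(e)
    return g, {e.key for e in passing}


BRAF_PROTOCOL = FilterCriteria(
    project="BROAD", scope="Skin",
    effectors={"expression", "tissue", "hotspot_mutation",
               "hotspot_co_mutation"},
    directions={"high_in_group"}, min_median=0.0, min_width=2, dashes=False)


def test_protocol_filter_returns_exactly_the_constructed_edges():
    graph, expected = _protocol_fixture()
    out = filter_cen(graph, BRAF_PROTOCOL)
    assert {e.key for e in out.edges} == expected


def test_filter_is_monotone_under_tightening():
    graph, _ = _protocol_fixture()
    base = filter_cen(graph, BRAF_PROTOCOL)
    for tighter in [
        FilterCriteria(**{**BRAF_PROTOCOL.__dict__, "min_width": 3}),
        FilterCriteria(**{**BRAF_PROTOCOL.__dict__, "min_median": 0.6}),
        FilterCriteria(**{**BRAF_PROTOCOL.__dict__,
                          "effectors": {"expression"}}),
        FilterCriteria(**{**BRAF_PROTOCOL.__dict__, "group_tiers": {"A"}}),
    ]:
        out = filter_cen(graph, tighter)
        assert {e.key for e in out.edges} <= {e.key for e in base.edges}


def test_extract_gene_cen_star_and_scope():
    g = CENGraph()
    for i, scope in enumerate(["Skin", "Skin", "Pancancer"]):
        g.add_edge(CENEdge(source="HUB", target=f"N{i}", project="P",
                           effector="coessentiality", comparision_in=scope,
                           higher=None, median_group=None, p_value=0.001,
                           correlation=0.9, width=3, dashes=False,
                           group_tier="A"))
    g.add_edge(CENEdge(source="X", target="Y", project="P",
                       effector="coessentiality", comparision_in="Skin",
                       higher=None, median_group=None, p_value=0.001,
                       correlation=0.9, width=3, dashes=False, group_tier="A"))
    sub = extract_gene_cen(g, "HUB")
    assert sub.nodes == {"HUB", "N0", "N1", "N2"}
    scoped = extract_gene_cen(g, "HUB", scope="Skin")
    assert {e.target for e in scoped.edges} == {"N0", "N1"}
    with pytest.raises(KeyError):
        extract_gene_cen(g, "MISSING")
    # an extra gene list pulls in edges among the named genes only
    extra = extract_gene_cen(g, "HUB", extra_genes=["X", "Y"])
    assert {e.source for e in extra.edges} == {"HUB", "X"}
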