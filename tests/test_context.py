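import itertools

import numpy as np
import pandas as pd
import pytest

from cenkit import (ContextRejected, ContextSpec, ScreenMatrix,
                    coessentiality_topk, make_discrete_context)
from cenkit.context import (adjust_bh, group_tier,
                            test_continuous as pearson_assoc,
                            test_discrete as mannwhitney_assoc,
                            test_multigroup as kruskal_assoc)

from conftest import mannwhitney_exact_oracle


def _spec(test_ids, control_ids, name="mut"):
    return ContextSpec(kind="discrete", name=name,
                       context_type="hotspot_mutation", source_node="MUT",
                       test_ids=tuple(test_ids), control_ids=tuple(control_ids))


def _series(pairs):
    return pd.Series(dict(pairs), name="GENE")


def test_mannwhitney_separated_triples_exact_p():
    scores = _series([("t1", 3.0), ("t2", 4.0), ("t3", 5.0),
                      ("c1", 0.0), ("c2", 1.0), ("c3", 2.0)])
    res = mannwhitney_assoc(scores, _spec(["t1", "t2", "t3"], ["c1", "c2", "c3"]))
    assert res.statistic == 9.0
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.higher == "high_in_group"
    assert res.median_group == 4.0
    assert res.group_tier == "B"


def test_identical_groups_report_no_direction():
    scores = _series([(f"t{i}", v) for i, v in enumerate([1.0, 2.0, 3.0])]
                     + [(f"c{i}", v) for i, v in enumerate([1.0, 2.0, 3.0])])
    res = mannwhitney_assoc(scores, _spec(["t0", "t1", "t2"], ["c0", "c1", "c2"]))
    assert res.higher == "none"


def test_group_tier_is_a_pure_function_of_sizes():
    assert group_tier(6, 27) == "A"
    assert group_tier(3, 5) == "B"
    assert group_tier(2, 50) == "NA"
    assert group_tier(5, 6) == "B"


@pytest.mark.parametrize("n1,n2,with_ties", [
    (3, 3, False), (3, 8, False), (5, 5, True), (8, 8, True), (4, 7, True)])
def test_exact_p_matches_exhaustive_enumeration(n1, n2, with_ties):
    rng = np.random.default_rng(n1 * 10 + n2)
    for _ in range(3):
        if with_ties:
            t = rng.integers(0, 4, n1).astype(float)
            c = rng.integers(0, 4, n2).astype(float)
        else:
            vals = rng.permutation(np.arange(n1 + n2, dtype=float))
            t, c = vals[:n1], vals[n1:]
        scores = _series([(f"t{i}", v) for i, v in enumerate(t)]
                         + [(f"c{i}", v) for i, v in enumerate(c)])
        res = mannwhitney_assoc(scores, _spec([f"t{i}" for i in range(n1)],
                                          [f"c{i}" for i in range(n2)]))
        expected = mannwhitney_exact_oracle(t, c)
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        if not with_ties:
            # without ties the null is symmetric, so the enumeration must
            # also agree with scipy's exact distribution
            from scipy.stats import mannwhitneyu
            ref = mannwhitneyu(t, c, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_groups_below_three_are_suppressed():
    scores = _series([("t0", 1.0), ("t1", np.nan), ("t2", 2.0),
                      ("c0", 0.0), ("c1", 0.5), ("c2", 0.7)])
    # after dropping the missing value the test group has 2 members
    res = mannwhitney_assoc(scores, _spec(["t0", "t1", "t2"], ["c0", "c1", "c2"]))
    assert res is None


def test_kruskal_needs_three_groups_and_detects_a_shift():
    rng = np.random.default_rng(0)
    ids = {g: [f"{g}{i}" for i in range(10)] for g in "abc"}
    null_hits = alt_hits = 0
    n_rep = 100
    for rep in range(n_rep):
        vals = {g: rng.normal(0, 1, 10) for g in "abc"}
        scores = _series([(f"{g}{i}", v) for g in "abc"
                          for i, v in enumerate(vals[g])])
        _, p = kruskal_assoc(scores, ids)
        null_hits += p > 0.05
        vals["c"] = vals["c"] + 5.0
        scores = _series([(f"{g}{i}", v) for g in "abc"
                          for i, v in enumerate(vals[g])])
        _, p = kruskal_assoc(scores, ids)
        alt_hits += p < 0.01
    assert null_hits / n_rep >= 0.90
    assert alt_hits / n_rep >= 0.95
    with pytest.raises(ValueError, match="test_discrete"):
        kruskal_assoc(scores, {"a": ids["a"], "b": ids["b"]})


def _cont_spec(covariate):
    return ContextSpec(kind="continuous", name="expr", context_type="expression",
                       source_node="GENE", covariate=covariate)


def test_pearson_perfect_linear_covariate():
    scores = _series([(f"c{i}", float(i)) for i in range(6)])
    res = pearson_assoc(scores, _cont_spec({f"c{i}": 2.0 * i + 1 for i in range(6)}))
    assert res.correlation == pytest.approx(1.0)


def test_pearson_closed_form_fixture():
    scores = _series([(f"c{i}", v) for i, v in enumerate([1, 2, 3, 4, 5])])
    res = pearson_assoc(scores, _cont_spec(
        {f"c{i}": v for i, v in enumerate([2, 1, 4, 3, 5])}))
    assert res.correlation == pytest.approx(0.8, abs=1e-12)
    # closed form: t = r sqrt((n-2)/(1-r^2)), p two-sided on t_{n-2}
    from scipy.stats import t as tdist
    t_stat = 0.8 * np.sqrt(3 / (1 - 0.64))
    assert res.p_value == pytest.approx(2 * tdist.sf(t_stat, 3), rel=1e-9)


def test_pearson_needs_five_pairs_and_variance():
    scores = _series([(f"c{i}", float(i)) for i in range(4)])
    assert pearson_assoc(scores, _cont_spec(
        {f"c{i}": float(i) for i in range(4)})) is None
    scores = _series([(f"c{i}", 1.0) for i in range(6)])
    assert pearson_assoc(scores, _cont_spec(
        {f"c{i}": float(i) for i in range(6)})) is None


@pytest.fixture()
def skin_panel():
    n_skin_mut, n_skin_wt, n_other = 6, 27, 10
    cells = ([f"SM{i}" for i in range(n_skin_mut)]
             + [f"SW{i}" for i in range(n_skin_wt)]
             + [f"O{i}" for i in range(n_other)])
    annotations = pd.DataFrame({
        "cell_line": cells,
        "tissue": ["Skin"] * (n_skin_mut + n_skin_wt) + ["Lung"] * n_other,
        "cancer_type": ["Melanoma"] * (n_skin_mut + n_skin_wt)
        + ["NSCLC"] * n_other,
        "msi_status": ["MSS"] * len(cells),
        "growth_property": ["Adherent"] * len(cells),
    })
    mutations = pd.DataFrame({
        "cell_line": [f"SM{i}" for i in range(n_skin_mut)] + ["O0"],
        "gene": ["NRAS"] * (n_skin_mut + 1),
        "protein_change": ["p.Q61K"] * (n_skin_mut + 1),
        "annotation_source": ["hotspot"] * (n_skin_mut + 1),
    })
    return annotations, mutations


def test_mutation_context_within_tissue_group_sizes(skin_panel):
    annotations, mutations = skin_panel
    spec = make_discrete_context(annotations, mutations, kind="mutation",
                                 gene="NRAS", scope="tissue:Skin")
    assert len(spec.test_ids) == 6 and len(spec.control_ids) == 27
    assert spec.comparison_in == "tissue:Skin"


def test_tissue_context_pancancer_split(skin_panel):
    annotations, _ = skin_panel
    spec = make_discrete_context(annotations, kind="tissue", value="Skin")
    assert len(spec.test_ids) == 33 and len(spec.control_ids) == 10


def test_small_mutant_group_is_rejected(skin_panel):
    annotations, mutations = skin_panel
    mutations = mutations.iloc[:2]  # only two carriers left
    with pytest.raises(ContextRejected, match="minimum"):
        make_discrete_context(annotations, mutations, kind="mutation",
                              gene="NRAS", scope="tissue:Skin")


def test_coessentiality_duplicate_gene_ranks_first():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(10, 12)),
                      index=[f"G{i}" for i in range(10)],
                      columns=[f"c{j}" for j in range(12)])
    df.loc["TWIN"] = df.loc["G0"]
    top = coessentiality_topk(ScreenMatrix(df, "scaled"), "G0")
    assert top.iloc[0]["gene"] == "TWIN"
    assert top.iloc[0]["r"] == pytest.approx(1.0)
    assert len(top) == 10  # default k


def test_coessentiality_matches_brute_force_ranking():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(size=(10, 15)),
                      index=[f"G{i}" for i in range(10)],
                      columns=[f"c{j}" for j in range(15)])
    sm = ScreenMatrix(df, "scaled")
    top = coessentiality_topk(sm, "G3", k=9)
    from scipy.stats import pearsonr
    brute = sorted(((pearsonr(df.loc["G3"], df.loc[g])[0], g)
                    for g in df.index if g != "G3"), key=lambda t: (-t[0], t[1]))
    assert top["gene"].tolist() == [g for _, g in brute]
    np.testing.assert_allclose(top["r"].to_numpy(),
                               [r for r, _ in brute], atol=1e-12)


def test_constant_query_vector_is_an_error():
    df = pd.DataFrame({f"c{j}": [1.0, j] for j in range(6)},
                      index=["FLAT", "VAR"])
    with pytest.raises(ValueError, match="constant"):
        coessentiality_topk(ScreenMatrix(df, "scaled"), "FLAT")


def test_bh_adjustment_preserves_order_and_never_decreases():
    p = pd.Series([0.001, 0.01, 0.02, 0.5, 0.04], index=list("abcde"))
    fdr = adjust_bh(p)
    assert (fdr >= p - 1e-15).all()
    # order of significance preserved
    assert fdr.loc[p.sort_values().index].is_monotonic_increasing
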