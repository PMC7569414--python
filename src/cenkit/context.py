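"""Group-wise association testing between gene essentiality and contexts.

Discrete contexts (tissue, cancer type, mutation status, MSI) split the cell
lines into a test and a control group and are tested with a two-sided
Mann-Whitney U (exact enumeration when both groups have at most 8 members,
tie-corrected normal approximation otherwise) or Kruskal-Wallis for three or
more groups.  Continuous contexts (expression, drug response) use Pearson
correlation with at least five paired observations.  All tests are
two-sided; the direction of a discrete association is reported separately
through the ``higher`` field.

Associations are tiered by per-group sample size: Group A requires at least
six cell lines in each group, Group B three to five.  Groups smaller than
three are not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ScreenMatrix

logger = logging.getLogger(__name__)

MIN_GROUP = 3          # smallest group ever tested
GROUP_A_MIN = 6        # Group A tier: at least six per group
MIN_CORRELATION_N = 5  # smallest sample for correlation tests

CONTEXT_TYPES = ("tissue", "cancer", "hotspot_mutation", "oncogenic_mutation",
                 "msi", "expression", "drug", "coessentiality")


class ContextRejected(ValueError):
    """A context definition yields groups too small (or empty) to test."""


@dataclass
class ContextSpec:
    """A test/control split (discrete) or covariate (continuous).

    ``comparison_in`` records the scope of the comparison: "Pancancer" or
    "tissue:<name>" / "cancer:<name>".  ``context_type`` drives the CEN edge
    effector; ``source_node`` is the context's node in the network (a tissue
    name, a mutated gene, an expressed gene, ...).
    """

    kind: str                       # "discrete" | "continuous"
    name: str
    context_type: str
    comparison_in: str = "Pancancer"
    source_node: str | None = None
    test_ids: tuple[str, ...] = ()
    control_ids: tuple[str, ...] = ()
    covariate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown context kind {self.kind!r}")
        if self.context_type not in CONTEXT_TYPES:
            raise ValueError(f"unknown context type {self.context_type!r}")
        if self.kind == "discrete":
            overlap = set(self.test_ids) & set(self.control_ids)
            if overlap:
                raise ValueError(f"test and control overlap: {sorted(overlap)[:5]}")
        elif not any(np.isfinite(v) for v in self.covariate.values()):
            raise ValueError("continuous context needs >= 1 finite covariate value")


@dataclass
class AssociationResult:
    """Outcome of testing one gene against one context."""

    gene: str
    context: ContextSpec
    statistic: float
    p_value: float
    correlation: float | None = None
    higher: str | None = None       # high_in_group | low_in_group | none
    median_group: float | None = None
    n_test: int = 0
    n_control: int = 0
    group_tier: str = "NA"


def group_tier(n_test: int, n_control: int) -> str:
    """Confidence tier from the two group sizes (pure function)."""
    smallest = min(n_test, n_control)
    if smallest >= GROUP_A_MIN:
        return "A"
    if MIN_GROUP <= smallest <= GROUP_A_MIN - 1:
        return "B"
    return "NA"


# ---------------------------------------------------------------------------
# Context construction
# ---------------------------------------------------------------------------

def _scope_ids(annotations: pd.DataFrame, scope: str) -> list[str]:
    if scope == "Pancancer":
        return list(annotations["cell_line"])
    prefix, _, value = scope.partition(":")
    if prefix == "tissue":
        mask = annotations["tissue"] == value
    elif prefix == "cancer":
        mask = annotations["cancer_type"] == value
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return list(annotations.loc[mask, "cell_line"])


def make_discrete_context(annotations: pd.DataFrame,
                          mutations: pd.DataFrame | None = None,
                          *, kind: str, value: str | None = None,
                          gene: str | None = None,
                          annotation_source: str = "hotspot",
                          scope: str = "Pancancer") -> ContextSpec:
    """Build a discrete context from annotation/mutation tables.

    ``kind`` is "tissue", "cancer", "msi" or "mutation".  For tissue/cancer
    contexts the named group is the test group and everything else in scope
    the control.  For mutation contexts the carriers of a mutation in
    ``gene`` (restricted to ``annotation_source``) form the test group.
    Contexts whose test or control group is smaller than three cell lines
    are rejected.
    """
    in_scope = _scope_ids(annotations, scope)
    ann = annotations.set_index("cell_line").loc[in_scope]

    if kind in ("tissue", "cancer"):
        column = "tissue" if kind == "tissue" else "cancer_type"
        test = [c for c in in_scope if ann.loc[c, column] == value]
        name = f"{kind}:{value}"
        source = value
        context_type = kind
    elif kind == "msi":
        test = [c for c in in_scope if ann.loc[c, "msi_status"] == "MSI"]
        name, source, context_type = "msi:MSI", "MSI", "msi"
    elif kind == "mutation":
        if mutations is None or gene is None:
            raise ValueError("mutation context needs a mutation table and a gene")
        gene = gene.upper()
        sub = mutations[(mutations["gene"] == gene)
                        & (mutations["annotation_source"] == annotation_source)]
        carriers = set(sub["cell_line"])
        test = [c for c in in_scope if c in carriers]
        context_type = ("hotspot_mutation" if annotation_source == "hotspot"
                        else "oncogenic_mutation")
        name = f"{context_type}:{gene}"
        source = gene
    else:
        raise ValueError(f"unknown discrete context kind {kind!r}")

    control = [c for c in in_scope if c not in set(test)]
    if len(test) < MIN_GROUP or len(control) < MIN_GROUP:
        raise ContextRejected(
            f"{name} in {scope}: group sizes {len(test)}/{len(control)} "
            f"below the minimum of {MIN_GROUP}")
    return ContextSpec(kind="discrete", name=name, context_type=context_type,
                       comparison_in=scope if scope != "Pancancer" else "Pancancer",
                       source_node=source, test_ids=tuple(test),
                       control_ids=tuple(control))


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

_EXACT_MAX = 8


def _exact_mannwhitney(test: np.ndarray, control: np.ndarray
                       ) -> tuple[float, float]:
    """Exhaustive-permutation two-sided Mann-Whitney U.

    Enumerates every split of the pooled observations into the observed
    group sizes and counts splits whose U lies at least as far from the null
    mean n1*n2/2 as the observed U.  Average ranks handle ties; with ties
    the permutation null of U need not be symmetric, which is why the
    two-sided p is defined on |U - n1*n2/2| rather than as twice a tail.
    """
    import itertools

    pooled = np.concatenate([test, control])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(test), len(control)
    mu = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    idx = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    u_all = ranks[idx].sum(axis=1) - offset
    p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
    return u_obs, p


def _mannwhitney(test: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration when both groups <= 8,
    tie-corrected normal approximation otherwise."""
    if len(test) <= _EXACT_MAX and len(control) <= _EXACT_MAX:
        return _exact_mannwhitney(test, control)
    res = stats.mannwhitneyu(test, control, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def test_discrete(gene_scores: pd.Series, context: ContextSpec,
                  gene: str | None = None) -> AssociationResult | None:
    """Mann-Whitney U test of one gene's scores between test and control.

    Missing scores are dropped per group and the sizes re-evaluated; a group
    smaller than three after dropping suppresses the result (returns None).
    """
    gene = gene or str(gene_scores.name)
    t = gene_scores.reindex(list(context.test_ids)).dropna().to_numpy(float)
    c = gene_scores.reindex(list(context.control_ids)).dropna().to_numpy(float)
    if len(t) < MIN_GROUP or len(c) < MIN_GROUP:
        logger.debug("%s vs %s untested: groups %d/%d", gene, context.name,
                     len(t), len(c))
        return None
    u, p = _mannwhitney(t, c)
    med_t, med_c = float(np.median(t)), float(np.median(c))
    if med_t > med_c:
        higher = "high_in_group"
    elif med_t < med_c:
        higher = "low_in_group"
    else:
        higher = "none"
    return AssociationResult(gene=gene, context=context, statistic=u, p_value=p,
                             higher=higher, median_group=med_t,
                             n_test=len(t), n_control=len(c),
                             group_tier=group_tier(len(t), len(c)))


def test_multigroup(gene_scores: pd.Series,
                    partition: dict[str, list[str]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across three or more disjoint groups.

    Two groups should go through :func:`test_discrete` instead.
    """
    if len(partition) < 3:
        raise ValueError("Kruskal-Wallis needs >= 3 groups; use test_discrete "
                         "for two-group comparisons")
    samples = []
    for name, ids in partition.items():
        vals = gene_scores.reindex(ids).dropna().to_numpy(float)
        if len(vals) < MIN_GROUP:
            raise ContextRejected(f"group {name!r} has {len(vals)} finite scores "
                                  f"(minimum {MIN_GROUP})")
        samples.append(vals)
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def test_continuous(gene_scores: pd.Series, context: ContextSpec,
                    gene: str | None = None) -> AssociationResult | None:
    """Pearson correlation between scores and a continuous covariate.

    Requires at least five cell lines with both values finite; zero variance
    in either vector suppresses the result.
    """
    gene = gene or str(gene_scores.name)
    cov = pd.Series(context.covariate, dtype=float)
    joined = pd.concat([gene_scores.rename("score"), cov.rename("cov")],
                       axis=1, join="inner").dropna()
    if len(joined) < MIN_CORRELATION_N:
        logger.debug("%s vs %s untested: only %d paired values", gene,
                     context.name, len(joined))
        return None
    x = joined["score"].to_numpy(float)
    y = joined["cov"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("%s vs %s untested: zero variance", gene, context.name)
        return None
    r, p = stats.pearsonr(x, y)
    n = len(joined)
    return AssociationResult(gene=gene, context=context, statistic=float(r),
                             p_value=float(p), correlation=float(r),
                             n_test=n, n_control=n, group_tier=group_tier(n, n))


def coessentiality_topk(matrix: ScreenMatrix, gene: str, k: int = 10,
                        scope: list[str] | None = None) -> pd.DataFrame:
    """Top-k co-essential partners of ``gene`` by Pearson correlation.

    Correlations are computed between the query gene's score vector and every
    other gene's over the scoped cell lines (pairwise-complete); self is
    excluded and ties in r break alphabetically.
    """
    gene = gene.upper()
    if gene not in matrix.data.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    data = matrix.data[scope] if scope is not None else matrix.data
    if data.shape[1] < MIN_CORRELATION_N:
        raise ValueError(f"scope has {data.shape[1]} cell lines "
                         f"(minimum {MIN_CORRELATION_N})")
    query = data.loc[gene]
    if query.dropna().nunique() <= 1:
        raise ValueError(f"query gene {gene!r} has a constant score vector")

    rows = []
    for other in data.index:
        if other == gene:
            continue
        pair = pd.concat([query.rename("q"), data.loc[other].rename("o")],
                         axis=1).dropna()
        n = len(pair)
        if n < MIN_CORRELATION_N or pair["o"].nunique() <= 1:
            continue
        r, p = stats.pearsonr(pair["q"], pair["o"])
        rows.append((other, float(r), float(p), n))
    df = pd.DataFrame(rows, columns=["gene", "r", "p_value", "n"])
    df = df.sort_values(["r", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.head(k)


def adjust_bh(p_values: pd.Series) -> pd.Series:
    """Optional Benjamini-Hochberg column for association tables."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(p_values.to_numpy(float), method="fdr_bh")[1]
    return pd.Series(adj, index=p_values.index, name="fdr")


# ---------------------------------------------------------------------------
# Result <-> table conversion (the CLI's exchange format)
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ("gene", "context_type", "context_name", "comparison_in",
                  "source_node", "statistic", "p_value", "correlation",
                  "higher", "median_group", "n_test", "n_control", "group_tier")


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "gene": r.gene,
            "context_type": r.context.context_type,
            "context_name": r.context.name,
            "comparison_in": r.context.comparison_in,
            "source_node": r.context.source_node,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "correlation": r.correlation,
            "higher": r.higher,
            "median_group": r.median_group,
            "n_test": r.n_test,
            "n_control": r.n_control,
            "group_tier": r.group_tier,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def frame_to_results(df: pd.DataFrame) -> list[AssociationResult]:
    out = []
    for _, row in df.iterrows():
        kind = ("continuous" if row["context_type"] in
                ("expression", "drug", "coessentiality") else "discrete")
        corr = row.get("correlation")
        ctx = ContextSpec(kind=kind, name=row["context_name"],
                          context_type=row["context_type"],
                          comparison_in=row["comparison_in"],
                          source_node=row.get("source_node"),
                          covariate={"_": 0.0} if kind == "continuous" else {})
        out.append(AssociationResult(
            gene=row["gene"], context=ctx, statistic=row["statistic"],
            p_value=row["p_value"],
            correlation=None if pd.isna(corr) else float(corr),
            higher=None if pd.isna(row.get("higher")) else row["higher"],
            median_group=(None if pd.isna(row.get("median_group"))
                          else float(row["median_group"])),
            n_test=int(row["n_test"]), n_control=int(row["n_control"]),
            group_tier=row["group_tier"]))
    return out
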