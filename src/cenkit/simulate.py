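"""Seeded synthetic CRISPR-screen panels with planted ground truth.

The generator emulates the statistical structure the pipeline assumes: a
gene x cell-line logFC matrix in which reference essential genes are
strongly depleted everywhere, reference non-essential genes are not, and
planted context-specific genes are depleted only in the cell lines carrying
their context (a tissue, a mutation, or high expression of a driver).
logFC noise is Gaussian — the minimal distributional assumption, which keeps
power calculations analytic.  Everything is driven by an integer-seeded
generator, so panels are fully deterministic across platforms.

Default panel: 2,000 genes x 60 cell lines across four tissues; 5% planted
core genes, 5% context-specific (tissue-restricted), 1% rare-context
(3-5 cell lines); depletion means -2.5 (essential) vs 0.0 (non-essential)
with noise sd 0.5 — effect sizes that exercise the pipeline's minimum group
sizes (3/6 per group, n >= 5 for correlations) on a panel that simulates in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import N_BINS, ProbabilityProfiles
from .io import ScreenMatrix
from .scaling import ReferenceGeneSets

DEFAULT_TISSUES = ("Skin", "Lung", "Breast", "CNS")


@dataclass
class PlantedContext:
    name: str
    kind: str                 # "tissue" | "rare"
    genes: tuple[str, ...]
    effect: float             # depletion shift in logFC units
    cell_lines: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Planted gene classes and context memberships of a synthetic panel."""

    classes: dict[str, str]                 # gene -> class
    contexts: list[PlantedContext]
    tissue_of: dict[str, str]               # cell line -> tissue

    def genes_in_class(self, label: str) -> set[str]:
        return {g for g, c in self.classes.items() if c == label}


def simulate_screen(n_genes: int = 2000, n_cells: int = 60,
                    core_fraction: float = 0.05,
                    context_fraction: float = 0.05,
                    rare_fraction: float = 0.01,
                    n_essential_ref: int | None = None,
                    n_nonessential_ref: int | None = None,
                    mu_essential: float = -2.5,
                    mu_nonessential: float = 0.0,
                    noise_sd: float = 0.5,
                    tissues: tuple[str, ...] = DEFAULT_TISSUES,
                    seed: int = 7
                    ) -> tuple[ScreenMatrix, SyntheticTruth, ReferenceGeneSets]:
    """Simulate a logFC screen with planted core/context/rare/non-essential genes.

    Reference and core genes draw logFC ~ N(mu_essential, noise_sd) in every
    cell line; non-essential genes (and non-essential references) draw
    N(mu_nonessential, noise_sd); context genes get the essential mean only
    in their planted context's cell lines.  Deterministic under ``seed``.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10 for the pipeline's minimum "
                         "group sizes")
    # reference sets default to 5% / 7.5% of the universe (>= 10 per class,
    # the logistic-fit minimum)
    if n_essential_ref is None:
        n_essential_ref = max(10, int(round(0.05 * n_genes)))
    if n_nonessential_ref is None:
        n_nonessential_ref = max(10, int(round(0.075 * n_genes)))
    if mu_essential >= mu_nonessential:
        raise ValueError("mu_essential must be below mu_nonessential")
    n_core = int(round(core_fraction * n_genes))
    n_ctx = int(round(context_fraction * n_genes))
    n_rare = int(round(rare_fraction * n_genes))
    n_special = n_core + n_ctx + n_rare + n_essential_ref + n_nonessential_ref
    if n_special > n_genes:
        raise ValueError("class fractions plus reference sets exceed the "
                         "gene universe")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cells = [f"CL{j:03d}" for j in range(n_cells)]
    tissue_of = {c: tissues[j % len(tissues)] for j, c in enumerate(cells)}

    order = list(rng.permutation(n_genes))
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        picked = [genes[i] for i in order[cursor:cursor + n]]
        cursor += n
        return picked

    ess_ref = take(n_essential_ref)
    non_ref = take(n_nonessential_ref)
    core = take(n_core)
    ctx = take(n_ctx)
    rare = take(n_rare)

    classes = {g: "non_essential" for g in genes}
    classes.update({g: "essential_ref" for g in ess_ref})
    classes.update({g: "nonessential_ref" for g in non_ref})
    classes.update({g: "core" for g in core})
    classes.update({g: "context_specific" for g in ctx})
    classes.update({g: "rare_context" for g in rare})

    X = rng.normal(mu_nonessential, noise_sd, size=(n_genes, n_cells))
    gene_pos = {g: i for i, g in enumerate(genes)}
    cell_pos = {c: j for j, c in enumerate(cells)}
    always = [gene_pos[g] for g in ess_ref + core]
    X[always, :] += mu_essential - mu_nonessential

    effect = mu_essential - mu_nonessential
    contexts: list[PlantedContext] = []
    tissue_members = {t: tuple(c for c in cells if tissue_of[c] == t)
                      for t in tissues}
    by_tissue: dict[str, list[str]] = {t: [] for t in tissues}
    for i, g in enumerate(ctx):
        t = tissues[i % len(tissues)]
        by_tissue[t].append(g)
        cols = [cell_pos[c] for c in tissue_members[t]]
        X[gene_pos[g], cols] += effect
    for t in tissues:
        if by_tissue[t]:
            contexts.append(PlantedContext(
                name=f"tissue:{t}", kind="tissue", genes=tuple(by_tissue[t]),
                effect=effect, cell_lines=tissue_members[t]))
    for g in rare:
        k = int(rng.integers(3, 6))  # 3-5 carrier lines
        carriers = tuple(sorted(rng.choice(cells, size=k, replace=False)))
        cols = [cell_pos[c] for c in carriers]
        X[gene_pos[g], cols] += effect
        contexts.append(PlantedContext(
            name=f"rare:{g}", kind="rare", genes=(g,), effect=effect,
            cell_lines=carriers))

    matrix = ScreenMatrix(pd.DataFrame(X, index=genes, columns=cells), "logfc")
    truth = SyntheticTruth(classes=classes, contexts=contexts,
                           tissue_of=tissue_of)
    refs = ReferenceGeneSets(frozenset(ess_ref), frozenset(non_ref))
    return matrix, truth, refs


@dataclass
class MutationPlan:
    gene: str
    fraction: float                       # carrier fraction within scope
    annotation_source: str = "hotspot"
    tissue: str | None = None             # restrict carriers to a tissue


@dataclass
class LineagePlan:
    gene: str
    tissue: str
    delta_expr: float = 3.0               # expression shift in the tissue


@dataclass
class ContextPlan:
    mutations: list[MutationPlan] = field(default_factory=list)
    lineage: list[LineagePlan] = field(default_factory=list)
    msi_fraction: float = 0.15


def simulate_contexts(truth: SyntheticTruth, plan: ContextPlan | None = None,
                      seed: int = 7
                      ) -> tuple[pd.DataFrame, pd.DataFrame, ScreenMatrix]:
    """Annotation, mutation and expression tables for a simulated panel.

    Tissue labels come from the panel's planted assignment; mutation plans
    flag a seeded random carrier fraction (0 means no carriers); lineage
    genes get elevated expression (shift ``delta_expr``) only in their
    tissue, emulating lineage-restricted expression-essentiality coupling.
    """
    plan = plan or ContextPlan()
    rng = np.random.default_rng(seed)
    cells = sorted(truth.tissue_of)
    genes = sorted(truth.classes)

    if not 0 <= plan.msi_fraction < 1:
        raise ValueError("msi_fraction must be in [0, 1)")
    annotations = pd.DataFrame({
        "cell_line": cells,
        "tissue": [truth.tissue_of[c] for c in cells],
        "cancer_type": [f"{truth.tissue_of[c]} carcinoma" for c in cells],
        "msi_status": np.where(rng.random(len(cells)) < plan.msi_fraction,
                               "MSI", "MSS"),
        "growth_property": np.where(rng.random(len(cells)) < 0.8,
                                    "Adherent", "Suspension"),
    })

    mut_rows = []
    for m in plan.mutations:
        if not 0 <= m.fraction < 1:
            raise ValueError(f"mutant fraction {m.fraction} outside [0, 1)")
        pool = [c for c in cells
                if m.tissue is None or truth.tissue_of[c] == m.tissue]
        n_mut = int(round(m.fraction * len(pool)))
        carriers = rng.choice(pool, size=n_mut, replace=False) if n_mut else []
        for c in sorted(carriers):
            mut_rows.append({"cell_line": c, "gene": m.gene.upper(),
                             "protein_change": "p.SIM1X",
                             "annotation_source": m.annotation_source})
    mutations = pd.DataFrame(mut_rows, columns=["cell_line", "gene",
                                                "protein_change",
                                                "annotation_source"])

    # baseline log(FPKM + 1) expression with per-gene means; lineage genes
    # shifted up only in their own tissue
    base = rng.uniform(1.0, 5.0, size=len(genes))
    expr = base[:, None] + rng.normal(0.0, 0.5, size=(len(genes), len(cells)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for lp in plan.lineage:
        cols = [j for j, c in enumerate(cells) if truth.tissue_of[c] == lp.tissue]
        expr[gene_pos[lp.gene], cols] += lp.delta_expr
    expr = np.clip(expr, 0.0, None)
    expression = ScreenMatrix(pd.DataFrame(expr, index=genes, columns=cells),
                              value_kind="logfc")
    return annotations, mutations, expression


#: bin indices (1-based) where the four archetype classes concentrate mass
ARCHETYPE_PEAKS = {"core": 20, "context_specific": 14, "rare_context": 6,
                   "non_essential": 1}
DEFAULT_PROFILE_FRACTIONS = (0.05, 0.05, 0.01, 0.89)


def simulate_archetype_profiles(n_profiles: int = 2000,
                                fractions: tuple[float, float, float, float]
                                = DEFAULT_PROFILE_FRACTIONS,
                                concentration: float = 50.0,
                                seed: int = 7
                                ) -> tuple[ProbabilityProfiles, pd.Series]:
    """20-bin profiles sampled around four planted archetypes.

    Each archetype concentrates 70% of its mass at one bin (20 / 14 / 6 / 1
    for core, context-specific, rare-context and non-essential) with the
    remainder spread uniformly; profiles are Dirichlet draws around the
    archetype with the given concentration.  Returns the profiles and the
    planted class of each profile.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = list(ARCHETYPE_PEAKS)
    counts = [int(round(f * n_profiles)) for f in fractions[:-1]]
    counts.append(n_profiles - sum(counts))

    rows, classes = [], []
    for label, count in zip(labels, counts):
        peak = ARCHETYPE_PEAKS[label] - 1
        arche = np.full(N_BINS, 0.3 / (N_BINS - 1))
        arche[peak] = 0.7
        rows.append(rng.dirichlet(concentration * arche, size=count))
        classes.extend([label] * count)
    freq = np.vstack(rows)
    index = [f"P{i:05d}" for i in range(n_profiles)]
    profiles = ProbabilityProfiles(
        pd.DataFrame(freq, index=index,
                     columns=[f"bin_{b + 1}" for b in range(N_BINS)]),
        pd.Series(np.full(n_profiles, np.nan), index=index, name="n_cells"))
    return profiles, pd.Series(classes, index=index, name="planted_class")
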