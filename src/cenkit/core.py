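"""Core-essentiality classification of genes from pooled CRISPR screens.

The classifier avoids hard logFC cut-offs and instead works in three steps:

1. Per cell line, a single-feature logistic regression is trained on the
   reference essential (label 1) and non-essential (label 0) genes, with the
   cell line's logFC as the feature, and applied to every gene to yield the
   probability that the gene is essential in that cell line.
2. Each gene's probabilities across cell lines are summarised as a 20-bin
   histogram over [0, 1], normalised to fractions, giving a length-20
   probability profile per gene.
3. The profiles are clustered with k-means; the number of clusters is chosen
   by maximising the mean silhouette score over candidate k, and clusters
   are labelled core-essential / context-specific / rare-context /
   non-essential by the expected probability of their centroids.

Core genes called independently in two projects are intersected to yield a
high-confidence core set.

The pipeline is exposed both as individual functions and as a
:class:`CoreEssentialityModel` whose :meth:`~CoreEssentialityModel.fit`
returns a :class:`CoreEssentialityResults` object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_samples, silhouette_score

from .io import ScreenMatrix
from .scaling import ReferenceGeneSets

logger = logging.getLogger(__name__)

N_BINS = 20
CLASS_LABELS = ("core_essential", "context_specific", "rare_context",
                "non_essential")


class FitError(RuntimeError):
    """A per-cell-line logistic fit failed or produced an inverted slope."""


def fit_cellline_models(matrix: ScreenMatrix, refs: ReferenceGeneSets,
                        min_refs: int = 10, ridge_c: float = 100.0
                        ) -> ScreenMatrix:
    """Fit one logistic regression per cell line and predict essentiality
    probabilities for every gene.

    The feature is the cell line's logFC; labels are 1 for essential and 0
    for non-essential reference genes; an intercept is included and a light
    ridge penalty (C = ``ridge_c``) guarantees convergence under perfect
    separation.  The fitted slope must be negative (lower logFC -> higher
    probability of essentiality); a non-negative slope is an error naming
    the cell line.  Reference genes receive their model-predicted
    probabilities like any other gene.
    """
    genes = matrix.data.index
    ess = sorted(refs.essential & set(genes))
    non = sorted(refs.non_essential & set(genes))
    if not ess or not non:
        raise FitError("reference sets absent from matrix")

    X = matrix.data.to_numpy(dtype=float)
    ess_idx = genes.get_indexer(ess)
    non_idx = genes.get_indexer(non)
    labels = np.concatenate([np.ones(len(ess)), np.zeros(len(non))])
    ref_idx = np.concatenate([ess_idx, non_idx])

    out = np.full_like(X, np.nan)
    for j, cell in enumerate(matrix.cell_lines):
        feat = X[ref_idx, j]
        mask = np.isfinite(feat)
        if (labels[mask] == 1).sum() < min_refs or (labels[mask] == 0).sum() < min_refs:
            raise FitError(f"cell line {cell!r}: fewer than {min_refs} finite "
                           "reference genes per class")
        clf = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=1000)
        clf.fit(feat[mask, None], labels[mask])
        slope = float(clf.coef_[0, 0])
        if slope >= 0:
            raise FitError(f"cell line {cell!r}: non-negative logistic slope "
                           f"({slope:.3g}); essential references are not depleted")
        col = X[:, j]
        fin = np.isfinite(col)
        out[fin, j] = clf.predict_proba(col[fin, None])[:, 1]

    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ScreenMatrix(df, value_kind="probability")


@dataclass
class ProbabilityProfiles:
    """Per-gene 20-bin frequency profiles of essentiality probabilities.

    ``freq`` has one row per gene and 20 columns of fractions summing to 1;
    ``n_cells`` counts the finite probabilities behind each row.
    """

    freq: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if self.freq.shape[1] < 2:
            raise ValueError("profiles need at least two bins")

    @property
    def n_bins(self) -> int:
        return self.freq.shape[1]


def bin_profiles(probs: ScreenMatrix, n_bins: int = N_BINS) -> ProbabilityProfiles:
    """Histogram each gene's probabilities into ``n_bins`` equal-width bins
    over [0, 1] (half-open bins, final bin closed), normalised to fractions.

    Genes with zero finite probabilities are excluded with a warning.
    """
    if probs.value_kind != "probability":
        raise ValueError("bin_profiles expects a probability matrix")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    P = probs.data.to_numpy(dtype=float)
    rows, counts, kept = [], [], []
    dropped = []
    for i, gene in enumerate(probs.genes):
        p = P[i][np.isfinite(P[i])]
        if p.size == 0:
            dropped.append(gene)
            continue
        hist, _ = np.histogram(p, bins=edges)  # final bin closed by np.histogram
        rows.append(hist / p.size)
        counts.append(p.size)
        kept.append(gene)
    if dropped:
        warnings.warn(f"excluded {len(dropped)} genes with no finite "
                      f"probabilities (e.g. {dropped[:3]})")
    freq = pd.DataFrame(rows, index=kept,
                        columns=[f"bin_{b + 1}" for b in range(n_bins)])
    return ProbabilityProfiles(freq, pd.Series(counts, index=kept, name="n_cells"))


@dataclass
class ClusterModel:
    """k-means clustering of probability profiles with silhouette diagnostics."""

    k: int
    centroids: np.ndarray
    assignments: pd.Series              # gene -> cluster index
    per_gene_silhouette: pd.Series      # gene -> si-score in [-1, 1]
    mean_silhouette_by_k: dict[int, float]
    labels: dict[int, str] = field(default_factory=dict)

    def label_of(self, gene: str) -> str:
        return self.labels[int(self.assignments.loc[gene])]


def cluster_profiles(profiles: ProbabilityProfiles,
                     k_candidates: range = range(2, 9),
                     seed: int = 0, n_restarts: int = 25) -> ClusterModel:
    """k-means over the profile matrix for each candidate k; the k with the
    highest mean silhouette (Euclidean) wins.

    Returns assignments, centroids and per-gene si-scores at the chosen k.
    """
    X = profiles.freq.to_numpy(dtype=float)
    ks = [k for k in k_candidates]
    if X.shape[0] <= max(ks):
        raise ValueError("need more profiles than the largest candidate k")

    fits: dict[int, KMeans] = {}
    mean_sil: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < k:
            raise RuntimeError(f"k-means produced an empty cluster at k={k}")
        fits[k] = km
        mean_sil[k] = float(silhouette_score(X, labels))
    best_k = max(ks, key=lambda k: (mean_sil[k], -k))
    km = fits[best_k]
    labels = km.labels_
    si = silhouette_samples(X, labels)
    model = ClusterModel(
        k=best_k,
        centroids=km.cluster_centers_,
        assignments=pd.Series(labels, index=profiles.freq.index, name="cluster"),
        per_gene_silhouette=pd.Series(si, index=profiles.freq.index, name="si_score"),
        mean_silhouette_by_k=mean_sil,
    )
    return label_clusters(model)


def label_clusters(model: ClusterModel) -> ClusterModel:
    """Label clusters by the expected probability of their centroids.

    Expected probability of a centroid is sum_b freq_b * midpoint(bin b).
    The highest-ranked centroid is core_essential and the lowest
    non_essential; remaining clusters are context tiers in rank order
    (higher expected probability -> context_specific, lower ->
    rare_context).  Ties break by mass in the last bin, then cluster index.
    """
    n_bins = model.centroids.shape[1]
    midpoints = (np.arange(n_bins) + 0.5) / n_bins
    expected = model.centroids @ midpoints
    order = sorted(range(model.k),
                   key=lambda c: (-expected[c], -model.centroids[c, -1], c))
    labels: dict[int, str] = {}
    labels[order[0]] = "core_essential"
    if model.k >= 2:
        labels[order[-1]] = "non_essential"
    middles = order[1:-1]
    n_ctx = (len(middles) + 1) // 2
    for rank, c in enumerate(middles):
        labels[c] = "context_specific" if rank < n_ctx else "rare_context"
    model.labels = labels
    return model


def high_confidence_core(core_a: set[str], core_b: set[str]) -> set[str]:
    """Exact intersection of the core calls from two independent projects.

    Genes with discordant cross-project profiles never enter the
    intersection because they are core in at most one project.
    """
    return set(core_a) & set(core_b)


# ---------------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------------

class CoreEssentialityModel:
    """Three-step core-essentiality classifier for one screen.

    Parameters
    ----------
    matrix : ScreenMatrix
        Corrected logFC matrix (genes x cell lines).  Scaled essentiality
        scores are accepted too (the logistic model is a monotone
        reparameterization); pass ``feature="scaled"`` to acknowledge it.
    refs : ReferenceGeneSets
        Gold-standard essential / non-essential reference genes.
    n_bins : int
        Number of probability histogram bins (default 20).
    """

    def __init__(self, matrix: ScreenMatrix, refs: ReferenceGeneSets,
                 n_bins: int = N_BINS, ridge_c: float = 100.0,
                 feature: str = "logfc") -> None:
        if feature not in ("logfc", "scaled"):
            raise ValueError("feature must be 'logfc' or 'scaled'")
        if feature == "logfc" and matrix.value_kind != "logfc":
            raise ValueError("matrix is not a logFC matrix; pass feature='scaled' "
                             "to fit on scaled scores")
        self.matrix = matrix
        self.refs = refs
        self.n_bins = n_bins
        self.ridge_c = ridge_c
        self.feature = feature

    def fit(self, k_candidates: range = range(2, 9), seed: int = 0,
            n_restarts: int = 25) -> "CoreEssentialityResults":
        probs = fit_cellline_models(self.matrix, self.refs, ridge_c=self.ridge_c)
        if self.feature == "scaled":
            # scaled scores grow with essentiality: flip so the slope-sign
            # contract (negative slope) still guards against label inversion
            flipped = ScreenMatrix(-self.matrix.data, value_kind="logfc")
            probs = fit_cellline_models(flipped, self.refs, ridge_c=self.ridge_c)
        profiles = bin_profiles(probs, n_bins=self.n_bins)
        clusters = cluster_profiles(profiles, k_candidates=k_candidates,
                                    seed=seed, n_restarts=n_restarts)
        return CoreEssentialityResults(self, probs, profiles, clusters)


class CoreEssentialityResults:
    """Fitted classification: probabilities, profiles, clusters and labels."""

    def __init__(self, model: CoreEssentialityModel, probabilities: ScreenMatrix,
                 profiles: ProbabilityProfiles, clusters: ClusterModel) -> None:
        self.model = model
        self.probabilities = probabilities
        self.profiles = profiles
        self.clusters = clusters

    @property
    def assignments(self) -> pd.DataFrame:
        """Per-gene cluster index, class label and silhouette score."""
        cl = self.clusters
        return pd.DataFrame({
            "cluster": cl.assignments,
            "label": cl.assignments.map(cl.labels),
            "si_score": cl.per_gene_silhouette,
        })

    def genes_in_class(self, label: str) -> set[str]:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class {label!r}")
        a = self.assignments
        return set(a.index[a["label"] == label])

    @property
    def core_genes(self) -> set[str]:
        return self.genes_in_class("core_essential")

    def summary(self) -> str:
        cl = self.clusters
        lines = [
            "Core-essentiality classification",
            "=" * 38,
            f"genes profiled        {len(self.profiles.freq):>8d}",
            f"cell lines            {len(self.probabilities.cell_lines):>8d}",
            f"chosen k              {cl.k:>8d}",
            f"mean silhouette       {cl.mean_silhouette_by_k[cl.k]:>8.3f}",
            "",
            "class counts",
            "-" * 38,
        ]
        counts = self.assignments["label"].value_counts()
        for label in CLASS_LABELS:
            lines.append(f"{label:<22s}{int(counts.get(label, 0)):>8d}")
        lines.append("")
        lines.append("mean silhouette by k: " + ", ".join(
            f"{k}={v:.3f}" for k, v in sorted(cl.mean_silhouette_by_k.items())))
        return "\n".join(lines)
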