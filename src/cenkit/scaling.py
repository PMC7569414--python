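"""Scaled essentiality scores from corrected log fold changes.

A screen's gene-level logFC matrix is first quantile normalised per sample
(cell line) and then median scaled against gold-standard reference essential
and non-essential gene sets, with a sign flip so that, within every cell
line, the median score of the essential references is exactly 1 and of the
non-essential references exactly 0.  Larger scores mean more essential.

For column c with reference medians m_e(c) (essential) and m_ne(c)
(non-essential), every logFC x maps to::

    score = (m_ne(c) - x) / (m_ne(c) - m_e(c))

which is affine per column: within-column rank order is preserved and the
sign of differences is reversed (more negative logFC -> larger score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ScreenMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceGeneSets:
    """Gold-standard essential / non-essential reference gene sets."""

    essential: frozenset[str]
    non_essential: frozenset[str]

    def __post_init__(self) -> None:
        ess = frozenset(g.upper() for g in self.essential)
        non = frozenset(g.upper() for g in self.non_essential)
        object.__setattr__(self, "essential", ess)
        object.__setattr__(self, "non_essential", non)
        if not ess or not non:
            raise ValueError("both reference sets must be non-empty")
        overlap = ess & non
        if overlap:
            raise ValueError(f"reference sets overlap: {sorted(overlap)[:5]}")


def quantile_normalize(matrix: ScreenMatrix) -> ScreenMatrix:
    """Quantile normalise each column (cell line) to a common distribution.

    The reference distribution is the mean of the per-column sorted values
    (the standard construction).  Ties within a column receive the mean of
    their reference slots (average ranks); per-column rank order is
    preserved.  Missing values stay missing; a column with no finite value
    is an error naming the cell line.
    """
    X = matrix.data.to_numpy(dtype=float, copy=True)
    n_genes, n_cells = X.shape
    if n_cells < 2 or n_genes < 2:
        raise ValueError("quantile normalization needs >= 2 genes and >= 2 cell lines")

    grid = np.linspace(0.0, 1.0, n_genes)
    col_quantiles = np.empty((n_genes, n_cells))
    for j in range(n_cells):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0:
            raise ValueError(f"cell line {matrix.cell_lines[j]!r} has no finite values")
        finite.sort()
        if finite.size == n_genes:
            col_quantiles[:, j] = finite
        else:
            pos = np.linspace(0.0, 1.0, finite.size)
            col_quantiles[:, j] = np.interp(grid, pos, finite)
    reference = col_quantiles.mean(axis=1)

    out = np.full_like(X, np.nan)
    for j in range(n_cells):
        col = X[:, j]
        mask = np.isfinite(col)
        m = int(mask.sum())
        ranks = rankdata(col[mask], method="average")  # 1..m, ties averaged
        if m == 1:
            out[mask, j] = reference[n_genes // 2]
            continue
        # fractional slot into the length-n reference; exact slots when m == n
        slots = (ranks - 1.0) / (m - 1.0) * (n_genes - 1.0)
        out[mask, j] = np.interp(slots, np.arange(n_genes), reference)

    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ScreenMatrix(df, value_kind="logfc")


def reference_medians(matrix: ScreenMatrix, refs: ReferenceGeneSets
                      ) -> tuple[pd.Series, pd.Series]:
    """Per-column medians of the essential and non-essential reference genes.

    Reference genes missing from the matrix are dropped with a logged count.
    """
    genes = set(matrix.genes)
    ess = sorted(refs.essential & genes)
    non = sorted(refs.non_essential & genes)
    n_missing = (len(refs.essential) - len(ess)) + (len(refs.non_essential) - len(non))
    if n_missing:
        logger.info("dropped %d reference genes absent from the matrix", n_missing)
    if not ess or not non:
        raise ValueError("no reference genes present in the matrix")
    m_e = matrix.data.loc[ess].median(axis=0, skipna=True)
    m_ne = matrix.data.loc[non].median(axis=0, skipna=True)
    bad = m_e.index[~np.isfinite(m_e) | ~np.isfinite(m_ne)].tolist()
    if bad:
        raise ValueError(f"columns without finite reference values: {bad}")
    return m_e, m_ne


def median_scale(matrix: ScreenMatrix, refs: ReferenceGeneSets) -> ScreenMatrix:
    """Scale each column so essential refs have median 1, non-essential 0."""
    m_e, m_ne = reference_medians(matrix, refs)
    denom = m_ne - m_e
    degenerate = denom.index[denom == 0].tolist()
    if degenerate:
        raise ValueError(f"degenerate columns (m_e == m_ne): {degenerate}")
    scaled = (m_ne - matrix.data) / denom
    return ScreenMatrix(scaled, value_kind="scaled")


def scale_screen(matrix: ScreenMatrix, refs: ReferenceGeneSets,
                 quantile: bool = True) -> ScreenMatrix:
    """Full scaling pipeline: quantile normalization then median scaling."""
    if quantile:
        matrix = quantile_normalize(matrix)
    return median_scale(matrix, refs)
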