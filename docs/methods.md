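# Methods

This note documents the statistical model behind `cenkit`, the parameters
that matter, the synthetic-data generator used throughout the test suite,
and the numerical and design choices that were genuinely open.

## Essentiality scaling

Gene-level log2 fold changes (logFC) from a pooled knockout screen are made
comparable across cell lines in two steps, applied per sample (cell line):

1. **Quantile normalisation.** Each column is mapped onto a common reference
   distribution, constructed as the mean of the per-column sorted values —
   the standard construction. Ties within a column receive the mean of their
   reference slots (average ranks), so per-column rank order is preserved.
   Columns with missing values are mapped through linear interpolation of
   the reference quantile function; when a column is complete this reduces
   exactly to slot assignment.
2. **Reference median scaling.** With per-column medians *mₑ* (essential
   references) and *mₙₑ* (non-essential references), every value *x* maps to
   `(mₙₑ − x)/(mₙₑ − mₑ)`. Because the transform is affine per column and
   medians commute with affine maps, the essential references land exactly
   at median 1 and the non-essential references exactly at median 0 in every
   column (the test suite checks this to 1 × 10⁻⁹). Larger scores mean more
   essential. A column in which the two reference medians coincide is
   degenerate and raises an error. Reference genes absent from the matrix
   are dropped from the median computation with a logged count, since
   different screening projects target slightly different gene universes.

## Core-essentiality classification

The classifier avoids hard logFC cut-offs:

1. **Per-cell-line logistic regression.** For each cell line a
   single-feature logistic regression (feature: the column's logFC; labels:
   1 for the essential references, 0 for the non-essential; intercept
   included) yields P(essential) for every gene, references included. A
   light ridge penalty (C = 100, L2, lbfgs) guarantees convergence even
   under perfect separation of the two reference classes — the regulariser
   is weak enough that predicted reference probabilities still saturate
   beyond 0.99/0.01 on separated columns. The fitted slope must be
   negative (deeper depletion → higher probability); a non-negative slope
   indicates an inverted or corrupted column and is a hard error naming the
   cell line.
2. **Probability profiles.** Each gene's probabilities across the panel are
   histogrammed into 20 equal-width bins over [0, 1] (half-open bins, final
   bin closed) and normalised to fractions, so panels of different sizes are
   comparable. Binning is order-invariant, so no explicit sorting step is
   needed. Equal-width rather than quantile bins were chosen: probabilities
   already live on a fixed, interpretable [0, 1] scale, and quantile bins
   would erase exactly the mass-at-the-extremes signal the clustering needs.
3. **Clustering and labelling.** k-means (Euclidean, 25 seeded restarts per
   candidate k, candidates 2–8) is run on the 20-dimensional frequency
   vectors; the k maximising the mean silhouette score wins, with ties
   broken toward the smaller k. Clusters are labelled by the expected
   probability of their centroid, Σ_b freq_b · midpoint(b): the highest is
   core-essential, the lowest non-essential, and intermediate clusters are
   context tiers in rank order (upper half context-specific, lower half
   rare-context). Ties break by mass in the final bin, then cluster index,
   so labelling is deterministic.

Core calls from two independently processed projects are intersected to give
a high-confidence core set; a gene with discordant profiles (essential in
one project, not in the other) is core in at most one project and therefore
never enters the intersection.

**What the silhouette selects depends on the panel.** On the default
synthetic screen the logFC distribution is sharply bimodal, so nearly all
profile mass sits in bins 1 and 20 and the sparser intermediate tiers merge
into the extreme clusters: the silhouette then prefers k = 2, while planted
core genes are still recovered essentially perfectly (the suite requires
≥ 95% recovery with ≤ 1% leakage of non-essential genes). When the
intermediate profiles are well populated — the four-archetype profile
generator used by `scripts/acceptance.py` — the silhouette robustly selects
k = 4. Real screens, with their broad spectrum of partial dependencies,
resemble the latter regime.

## Context association testing

Scaled essentiality scores are not normally distributed and groups are often
small, so non-parametric tests are used throughout; all tests are two-sided
and the direction of an effect is reported separately.

- **Discrete contexts** (tissue, cancer type, mutation carriers, MSI):
  two-sided Mann–Whitney U between test and control. When both groups have
  at most 8 members the p-value comes from exhaustive enumeration of all
  C(n₁+n₂, n₁) group assignments, counting assignments with
  |U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|; average ranks handle ties, and this
  |U − μ| definition is used because with ties the permutation null of U
  need not be symmetric, making "twice the smaller tail" ill-defined. For
  larger groups the tie-corrected normal approximation (with continuity
  correction) is used. Three or more groups go through Kruskal–Wallis.
- **Continuous contexts** (expression, drug response): Pearson correlation,
  two-sided p from the t distribution with n − 2 degrees of freedom,
  requiring at least five complete pairs and non-zero variance on both
  sides.
- **Group sizes.** No test is run with fewer than 3 observations per group
  after pairwise missing-value removal. Associations are tiered Group A
  (both groups ≥ 6) or Group B (smaller group 3–5); Group B results carry a
  caution flag downstream.
- **Multiple testing.** Raw p-values feed the network's confidence bands;
  an optional Benjamini–Hochberg column (`adjust_bh`) is available for users
  who want FDR control across an association table.
- **Co-essentiality.** The top-k (default 10) partners of a query gene by
  Pearson correlation of score vectors across the scoped cell lines, self
  excluded, ties broken alphabetically.

## CEN assembly

Each surviving association becomes one typed edge. Confidence levels
(`width`): discrete associations get 1 for p ∈ [0.01, 0.05), 2 for
p ∈ [0.001, 0.01), 3 for p < 0.001; continuous get 1 for |r| ∈ [0.4, 0.6)
with p < 0.05, 2 for |r| ∈ [0.6, 0.8), 3 for |r| ≥ 0.8. The two lower bands
follow the established edge-filter conventions for such networks; the
level-3 cut-offs are this package's own refinement and are configurable
(`ConfidenceBands`). Anything below band 1 emits no edge.

Tissues and cancer types are first-class nodes so group-wise edges are
representable. Self-loops are restricted to two meanings: a gene whose own
expression correlates with its own essentiality, and a driver whose own
hotspot mutation associates with its own essentiality; a hotspot association
between two different genes is typed `hotspot_co_mutation`. `dashes` encodes
the Group B sample-size caution flag, which is the per-edge reliability
marker the filters act on.

Filters (`FilterCriteria`) accept per-effector minima for median essentiality
and confidence, effector/direction/tier/scope/sign whitelists, and are
conjunctive and monotone (tightening any criterion can only remove edges).
Edges lacking a median or direction pass the corresponding filters, because
continuous edges genuinely have neither. Recommended presets: lenient
(median > 0–0.2, any confidence) for tissue contexts with many confounders,
medium (median > 0.3) for cancer-type contexts, stringent (median > 0.4,
confidence ≥ 2) for single-mutation contexts.

## PPI overlay and enrichment

A CEN node set is mapped onto a STRING-dialect edge list (undirected,
deduplicated keeping the maximum combined score, self-pairs dropped, default
threshold combined score ≥ 400). The induced subgraph keeps every query gene,
isolated ones as degree-0 nodes. Over-representation per gene set is the
hypergeometric upper tail P(overlap ≥ observed) with set members intersected
with the background first; Benjamini–Hochberg runs across all tested terms
and results are filtered at the requested FDR (0.05 for pathway-style
collections; protein-complex analyses conventionally use an adjusted-p
cut-off of 0.01 — the cut-off is a parameter). The default background is the
screen's targeted gene universe, the natural null for a targeted screen;
callers may pass the PPI universe instead.

## Synthetic data

`simulate_screen` plants a gene universe with fixed classes — reference
essential/non-essential sets (5% / 7.5% of the universe, at least 10 each),
5% core, 5% tissue-restricted context-specific, 1% rare-context genes
(3–5 carrier lines each) — across a panel of ≥ 10 cell lines split evenly
over four tissues. Essential states draw logFC from N(−2.5, 0.5²) and
non-essential from N(0, 0.5²); context genes get the essential mean only in
their context's cells. Gaussian noise is the minimal distributional
assumption and keeps power analytic; the defaults give the pipeline's
minimum group sizes (3/6 per group, n ≥ 5 for correlation) realistic work on
a 60-cell-line panel that simulates in milliseconds. `simulate_contexts`
derives matching annotation, mutation (seeded carrier fractions) and
log(FPKM+1) expression tables, with lineage genes shifted up (default +3)
only in their tissue.

What the generator does **not** emulate: guide-level count noise and
off-target effects, copy-number artefacts, screen dropout dynamics,
correlated gene modules, and heavy-tailed score distributions. Passing tests
therefore demonstrate the correctness of the statistical machinery under its
stated assumptions, not performance on real screens.

`simulate_archetype_profiles` synthesizes 20-bin profiles directly:
archetypes concentrate 70% of their mass at bin 20 (core), 14
(context-specific), 6 (rare-context) or 1 (non-essential) with the remainder
uniform, and profiles are Dirichlet draws (concentration 50) around their
archetype. Class fractions default to 0.05/0.05/0.01/0.89.

## Problem sizes and determinism

The test suite and the acceptance script use panels of 200–2,000 genes and
16–60 cell lines, 20 clustering replicates of 2,000 profiles, 1,000
null-calibration and 200 power replicates — sizes at which every check runs
in seconds to a couple of minutes on a single CPU while leaving the
statistics well resolved. All randomness flows through integer-seeded
`numpy` generators and seeded k-means restarts; CLI runs record their
parameters, seeds and input checksums in a manifest, and replaying a
manifest reproduces deterministic outputs byte-identically.

## Known limitations

- Single-context testing: associations are computed one context at a time,
  so co-occurring contexts (e.g. a mutation enriched in one tissue) can
  confound each other. Mixed-effect models with context covariates are out
  of scope; the network view plus the cell-line selector are the intended
  tools for spotting confounding.
- No gRNA-level preprocessing (copy-number correction, guide efficacy) —
  the input is assumed to be a corrected gene-level logFC matrix.
- Gene identifiers are taken at face value (uppercased official symbols);
  no identifier mapping is performed.
- The exact Mann–Whitney path enumerates up to C(16, 8) = 12,870 splits per
  test; it is intentionally limited to groups of ≤ 8.
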