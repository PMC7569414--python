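import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cenkit import ReferenceGeneSets, ScreenMatrix, simulate_screen


@pytest.fixture(scope="session")
def small_panel():
    """A small seeded synthetic panel shared across tests."""
    return simulate_screen(n_genes=300, n_cells=24, seed=3)


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame([[1.0, 4.0], [2.0, 6.0], [3.0, 8.0]],
                      index=["A", "B", "C"], columns=["c1", "c2"])
    return ScreenMatrix(df, "logfc")


def mannwhitney_exact_oracle(test, control):
    """Exhaustive-permutation two-sided Mann-Whitney p-value.

    Enumerates every assignment of the pooled observations into groups of
    the observed sizes and counts assignments whose U is at least as far
    from the null mean n1*n2/2 as the observed U (average ranks, so ties
    are handled).  Independent of any scipy code path.
    """
    from scipy.stats import rankdata

    test = np.asarray(test, float)
    control = np.asarray(control, float)
    pooled = np.concatenate([test, control])
    ranks = rankdata(pooled)
    n1, n2 = len(test), len(control)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = total = 0
    for subset in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def hypergeom_upper_oracle(k, N, K, n):
    """Exact combinatorial P(overlap >= k) for draws of n from N with K marked."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total
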