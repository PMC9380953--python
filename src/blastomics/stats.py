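"""Shared rank statistics.

The Wilcoxon rank-sum (Mann-Whitney) test is the work-horse of both the
lineage-signature search and the ST-vs-ICSI differential-expression
contrast. Two regimes are provided:

* ``wilcoxon_exact`` — full enumeration of the permutation null of the
  rank sum, valid with ties, used when both groups have at most
  ``EXACT_MAX_N`` observations;
* ``wilcoxon_asymptotic`` — tie-corrected normal approximation with
  continuity correction, vectorized across genes.

Both report a two-sided p-value defined as
``min(1, 2 * min(P(W <= w), P(W >= w)))`` under the permutation null.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_N = 8


def wilcoxon_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value by enumerating group assignments.

    Handles ties through midranks; cost is C(n1+n2, n1) sums, intended for
    n1, n2 <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in combinations(range(pooled.size), n1)]
    )
    # tolerate float fuzz in midrank sums
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_asymptotic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum test.

    ``x`` has shape (n1, g) and ``y`` (n2, g); one test per column.
    Returns the two-sided p-values (length g).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[0], y.shape[0]
    n = n1 + n2
    pooled = np.vstack([x, y])
    ranks = rankdata(pooled, axis=0)
    w = ranks[:n1].sum(axis=0)
    mu = n1 * (n + 1) / 2.0

    # tie correction: sum over tie groups of (t^3 - t), per column
    srt = np.sort(pooled, axis=0)
    tie_term = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        _, counts = np.unique(srt[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    d = w - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - 0.5 * np.sign(d)) / np.sqrt(sigma2)
    p = 2.0 * norm.sf(np.abs(z))
    # all-tied column: zero variance, no evidence
    p = np.where(sigma2 <= 0, 1.0, p)
    return np.minimum(p, 1.0)


def wilcoxon_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values, exact for small groups."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] <= EXACT_MAX_N and y.shape[0] <= EXACT_MAX_N:
        return np.array(
            [wilcoxon_exact(x[:, j], y[:, j]) for j in range(x.shape[1])]
        )
    return wilcoxon_asymptotic(x, y)


def bonferroni(p: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size if n_tests is None else n_tests
    return np.minimum(1.0, p * m)
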