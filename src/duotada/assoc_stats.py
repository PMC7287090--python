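"""Ancillary association statistics: Poisson burden test and set-overlap test.

These are the validation-side companions of the joint model: the Poisson
test asks whether one gene carries more DNMs than its mutation rate
predicts, and the permutation test asks whether two prioritized gene
lists overlap more than random sets of the same sizes would.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import OverlapTestResult

__all__ = ["poisson_gene_test", "permutation_overlap_test"]


def poisson_gene_test(count, mu, n_trios: int):
    """Upper-tail Poisson p-value P(X >= count) at null mean 2*n_trios*mu.

    A count of zero gives p = 1 by convention (nothing to test).
    """
    x = np.asarray(count)
    mus = np.asarray(mu, dtype=float)
    if np.any(x < 0) or np.any(mus < 0) or n_trios < 1:
        raise ValueError("count and mu must be >= 0 and n_trios >= 1")
    out = stats.poisson.sf(x - 1, 2.0 * n_trios * mus)
    return float(out) if np.isscalar(count) else out


def permutation_overlap_test(
    background_size: int,
    size_a: int,
    size_b: int,
    observed_overlap: int,
    n_perm: int = 10_000,
    seed: int = 0,
    strict: bool = True,
    keep_null: bool = False,
) -> OverlapTestResult:
    """Permutation p-value for the overlap of two gene sets.

    Each permutation draws two uniform subsets of the background without
    replacement and records their overlap m. The p-value is
    (#{m > m0} + 1) / (N + 1) with the default strict inequality;
    ``strict=False`` uses the conventional m >= m0. The null of m is
    hypergeometric(background_size, size_a, size_b).
    """
    if size_a > background_size or size_b > background_size:
        raise ValueError("set sizes cannot exceed the background")
    if not 0 <= observed_overlap <= min(size_a, size_b):
        raise ValueError("observed overlap must lie in [0, min(size_a, size_b)]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    # partial Fisher-Yates: the first size_* slots of a permuted background
    pool = np.arange(background_size)
    draws = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        a = _partial_shuffle(pool, size_a, rng)
        b = _partial_shuffle(pool, size_b, rng)
        draws[i] = np.intersect1d(a, b, assume_unique=True).size
    exceed = int(np.sum(draws > observed_overlap if strict else draws >= observed_overlap))
    p = (exceed + 1) / (n_perm + 1)
    return OverlapTestResult(
        observed=observed_overlap,
        n_perm=n_perm,
        p_value=p,
        null_draws=draws if keep_null else None,
    )


def _partial_shuffle(pool: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """First k elements of an in-place partial Fisher-Yates shuffle: O(k)."""
    n = pool.size
    idx = rng.integers(0, n - np.arange(k))
    out = np.empty(k, dtype=pool.dtype)
    for j in range(k):
        i = idx[j] + j
        pool[j], pool[i] = pool[i], pool[j]
        out[j] = pool[j]
    return out
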