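"""Statistical helpers shared by the simulation and comparison studies."""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata

__all__ = ["rank_sum_z", "bootstrap_label_p", "minimum_animals"]


def rank_sum_z(x, y) -> float:
    """Wilcoxon rank-sum z statistic (normal approximation, midranks).

    The rank sum W of sample ``x`` within the pooled data is standardised
    by its null mean and tie-corrected variance:
    var = n1*n2/12 * (N + 1 - sum(t^3 - t) / (N*(N-1))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    w = ranks[:n1].sum()
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return 0.0  # all pooled values identical
    return float((w - mean) / math.sqrt(var))


def bootstrap_label_p(
    x, y, draws: int = 10_000, seed=None, observed_z: float | None = None
) -> float:
    """Permutation p for the rank-sum z under shuffled group labels.

    Labels are reassigned at random over the pooled values keeping the
    group sizes fixed; the p-value is the fraction of draws whose |z|
    meets or exceeds the observed |z|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    if observed_z is None:
        observed_z = rank_sum_z(x, y)
    # z is monotone in the rank sum of group 1, so permute ranks directly
    n2 = n - n1
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    # vectorised label shuffles: argsort of uniform noise -> random permutations
    order = np.argsort(rng.random((draws, n)), axis=1)
    w_perm = ranks[order[:, :n1]].sum(axis=1)
    z_perm = np.abs((w_perm - mean) / math.sqrt(var))
    return float(np.mean(z_perm >= abs(observed_z)))


def minimum_animals(sessions: int) -> int:
    """Resource-equation sample size: ceil(10 / (s - 1) + 1) subjects for
    ``sessions`` repeated sessions per subject."""
    if sessions < 2:
        raise ValueError("need at least 2 sessions")
    return math.ceil(10.0 / (sessions - 1) + 1.0)
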