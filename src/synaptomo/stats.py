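"""Summary statistics and significance tests.

Enhancement index (clustered/random peak-response ratio), coefficient of
variation of per-vesicle peaks within a synapse, permutation-based
Spearman rank correlation, and the paired t test. Significance
conventions: * P < 0.05, ** P < 0.01, *** P < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["EnhancementRecord", "enhancement_index",
           "coefficient_of_variation", "spearman_permutation", "paired_t",
           "significance_stars"]


@dataclass
class EnhancementRecord:
    """Per-vesicle peak responses and nanocluster distances."""

    vesicle_id: int
    peak_open_random: float
    peak_open_clustered: float
    dist_to_psd_cluster_nm: float = float("nan")
    dist_to_az_cluster_nm: float = float("nan")
    dist_to_nanocolumn_nm: float = float("nan")

    @property
    def enhancement_index(self) -> float:
        return enhancement_index(self.peak_open_clustered,
                                 self.peak_open_random)

    @property
    def flagged(self) -> bool:
        """Undefined index (zero peak in the random configuration)."""
        return self.peak_open_random == 0.0


def enhancement_index(peak_clustered: float, peak_random: float) -> float:
    """Clustered-over-random peak-response ratio.

    Values above one mean AMPAR clustering potentiated the response to
    this fusion event; below one, it reduced it. NaN when the random
    peak is zero (flagged record).
    """
    if peak_random == 0.0:
        return float("nan")
    return float(peak_clustered) / float(peak_random)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation needs n >= 2")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def spearman_permutation(x, y, n_perm: int = 10_000, seed: int = 0
                         ) -> tuple[float, float]:
    """Spearman rho (midrank ties) with a two-sided permutation p-value.

    One variable is randomly permuted ``n_perm`` times; p is the
    fraction of permutations with ``|rho_perm| >= |rho_obs|`` (ties count,
    so the resolution floor is 1/n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(x)
    rho_obs = float(rx @ ry) / n
    rng = np.random.default_rng(seed)
    # permute the (centred, scaled) ranks of y; rho is then a dot product
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = rx @ rng.permutation(ry)
    perm /= n
    p = float(np.mean(np.abs(perm) >= abs(rho_obs) - 1e-12))
    return rho_obs, max(p, 1.0 / n_perm)


def paired_t(a, b) -> float:
    """Two-sided paired t-test p-value.

    Zero-variance differences are handled per contract: all-zero
    differences give p = 1 (no effect); a constant nonzero difference is
    degenerate (t undefined) and returns p = 0 with the caller expected
    to treat it as a flagged limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired samples must be equal length, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d, 0.0) else 0.0
    return float(sstats.ttest_rel(a, b).pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
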