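"""Pairwise linkage-disequilibrium (r^2) computation on genotype dosages.

r^2 is the squared Pearson correlation of 0/1/2 allele-B dosages across the
samples non-missing at both markers — the unphased (Burrows-composite
equivalent) measure that PLINK, SNeP and NeEstimator all use on chip data.
A zero-variance marker in a pair gives r^2 = 0.
"""
from __future__ import annotations

import numpy as np

from .dataset import MISSING


def r2_matrix(calls_a: np.ndarray, calls_b: np.ndarray | None = None):
    """All-pairs r^2 between the columns of ``calls_a`` and ``calls_b``.

    Missing calls are handled pairwise: each (i, j) entry uses only the
    samples called at both markers.  Returns ``(r2, n_pairs)`` where
    ``n_pairs[i, j]`` is that joint sample count.  Pairs with fewer than
    two joint samples or a zero-variance member get r^2 = 0.
    """
    A = np.asarray(calls_a, dtype=np.float64)
    B = A if calls_b is None else np.asarray(calls_b, dtype=np.float64)
    Ma = (A != MISSING).astype(np.float64)
    Mb = (B != MISSING).astype(np.float64)
    Xa = np.where(Ma > 0, A, 0.0)
    Xb = np.where(Mb > 0, B, 0.0)

    n = Ma.T @ Mb
    sa = Xa.T @ Mb          # sum of a over joint samples
    sb = Ma.T @ Xb
    saa = (Xa**2).T @ Mb
    sbb = Ma.T @ (Xb**2)
    sab = Xa.T @ Xb

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab - sa * sb / n
        var_a = saa - sa**2 / n
        var_b = sbb - sb**2 / n
        r2 = cov**2 / (var_a * var_b)
    bad = ~np.isfinite(r2) | (n < 2) | (var_a <= 0) | (var_b <= 0)
    r2 = np.where(bad, 0.0, r2)
    return r2, n


def r2_pair(calls: np.ndarray, i: int, j: int) -> float:
    """r^2 between marker columns ``i`` and ``j`` of a call matrix."""
    r2, _ = r2_matrix(calls[:, [i]], calls[:, [j]])
    return float(r2[0, 0])
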