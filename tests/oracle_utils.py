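"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the ROH oracle
enumerates every subinterval on an (i, j) grid, the r^2 oracle loops over
pairs with plain numpy.corrcoef, and the window-pruning checker re-tests
every retained pair exhaustively.
"""
from __future__ import annotations

import numpy as np

from divkit.dataset import MISSING


def brute_force_roh(calls, pos, min_snp, max_gap_bp, min_length_bp):
    """All maximal qualifying homozygous runs for one individual on one
    chromosome, by exhaustive O(n^2) subinterval enumeration.

    Returns a set of (start_idx, end_idx, n_snp) tuples.
    """
    calls = np.asarray(calls)
    pos = np.asarray(pos)
    n = len(pos)
    if n == 0:
        return set()
    ok = (calls == 0) | (calls == 2)
    cum_bad = np.concatenate([[0], np.cumsum(~ok)])
    gap_bad = np.concatenate([[False], np.diff(pos) > max_gap_bp])
    cum_gap = np.concatenate([[0], np.cumsum(gap_bad)])

    I, J = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    block_ok = (J >= I) & (cum_bad[J + 1] - cum_bad[I] == 0)
    # gaps strictly inside the block are gap_bad at indices i+1..j
    block_ok &= (cum_gap[J + 1] - cum_gap[I + 1]) == 0

    ok_pad = np.concatenate([ok, [False]])
    gap_pad = np.concatenate([gap_bad, [False]])
    can_left = (I > 0) & ok_pad[np.maximum(I - 1, 0)] & ~gap_pad[I]
    can_right = (J < n - 1) & ok_pad[np.minimum(J + 1, n - 1)] & ~gap_pad[np.minimum(J + 1, n - 1)]
    maximal = block_ok & ~can_left & ~can_right

    qualify = maximal & (J - I + 1 >= min_snp) & (pos[J] - pos[I] >= min_length_bp)
    ii, jj = np.nonzero(qualify)
    return {(int(i), int(j), int(j - i + 1)) for i, j in zip(ii, jj)}


def naive_r2(x, y):
    """Squared Pearson correlation over jointly called samples, via
    numpy.corrcoef on the masked vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = (x != MISSING) & (y != MISSING)
    x, y = x[m], y[m]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def window_violations(ds, retained_ids, r2_max, window, step):
    """Exhaustively re-check the LD-pruning post-condition: count retained
    pairs exceeding r2_max inside any sliding window of retained markers."""
    ids = ds.markers["id"].tolist()
    keep = [i for i, mid in enumerate(ids) if mid in set(retained_ids)]
    chrom = ds.markers["chrom"].to_numpy(dtype=object)
    bad = 0
    for c in np.unique(chrom):
        cidx = [i for i in keep if chrom[i] == c]
        start = 0
        while start < len(cidx):
            win = cidx[start : start + window]
            for a in range(len(win)):
                for b in range(a + 1, len(win)):
                    if naive_r2(ds.calls[:, win[a]], ds.calls[:, win[b]]) > r2_max:
                        bad += 1
            start += step
    return bad
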