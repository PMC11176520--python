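"""Effective population size from linkage disequilibrium.

Two estimators operate on genotype-dosage r^2:

*Historical trajectory* (SNeP-style).  Intrachromosomal marker pairs are
binned by physical distance; each bin's mean r^2, corrected for finite
sample size (minus 1/n), is inverted through the drift expectation
E[r^2] = 1 / (alpha + 4 Ne c) (Sved), giving

    Ne(c) = (1 / 4c) * (1 / r2_adj - alpha),    t = 1 / (2c)

generations ago, with recombination fraction c obtained from physical
distance via a linear map function (default 1 cM/Mb, c = d_bp * 1e-8).
alpha = 1 is the mutation-free drift expectation; alpha = 2.2 (the
default, as in SNeP) adjusts for mutation.

*Contemporary point estimate* (NeEstimator-style, Waples & Do LD method,
random-mating coefficients).  Mean r^2 over unlinked pairs (markers on
different chromosomes), minus the expected sampling contribution
E(r^2_sample), is inverted with the weighted-regression coefficients of
Waples (2006); the two sample-size regimes split at a harmonic-mean
sample size S of 30.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .ld import r2_matrix


@dataclass
class NeBin:
    d_lo_bp: float
    d_hi_bp: float
    c: float          # recombination fraction at the bin midpoint
    t: float          # generations ago, 1/(2c)
    n_pairs: int
    mean_r2: float
    r2_adj: float
    ne: float


@dataclass
class ContemporaryNeResult:
    s_harmonic: float     # harmonic-mean per-pair sample size
    n_pairs: int
    mean_r2: float
    expected_sampling_r2: float
    r2_drift: float
    ne: float             # may be math.inf


def _intrachrom_pairs(ds: GenotypeDataset, min_bp: float, max_bp: float):
    """Distances and r^2 for all intrachromosomal pairs within range.

    Returns (distances_bp, r2) flat arrays.
    """
    chrom = ds.markers["chrom"].to_numpy(dtype=object)
    pos = ds.markers["pos"].to_numpy()
    dists, r2s = [], []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if len(idx) < 2:
            continue
        r2, _ = r2_matrix(ds.calls[:, idx])
        cpos = pos[idx].astype(float)
        d = np.abs(cpos[:, None] - cpos[None, :])
        iu = np.triu_indices(len(idx), k=1)
        d, r2 = d[iu], r2[iu]
        keep = (d >= min_bp) & (d <= max_bp)
        dists.append(d[keep])
        r2s.append(r2[keep])
    if not dists:
        return np.array([]), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def historical_ne(
    ds: GenotypeDataset,
    n_bins: int = 50,
    min_bp: float = 25_000,
    max_bp: float = 25_000_000,
    alpha: float = 2.2,
    cm_per_mb: float = 1.0,
    min_pairs: int = 50,
    map_function: str = "linear",
) -> pd.DataFrame:
    """Historical Ne trajectory from binned intrachromosomal LD decay.

    Bins are equal-width over [min_bp, max_bp]; bins with fewer than
    ``min_pairs`` pairs or non-positive adjusted r^2 are dropped with a
    warning.  ``map_function`` converts Morgan distance to a recombination
    fraction: "linear" (c = d, the 1 cM/Mb convention) or "haldane"
    (c = (1 - exp(-2d))/2).  Returns a table (d_lo_bp, d_hi_bp, c, t,
    n_pairs, mean_r2, r2_adj, ne) sorted by t.
    """
    if map_function not in ("linear", "haldane"):
        raise ValueError("map_function must be 'linear' or 'haldane'")
    d, r2 = _intrachrom_pairs(ds, min_bp, max_bp)
    edges = np.linspace(min_bp, max_bp, n_bins + 1)
    n = ds.n_samples
    rows = []
    dropped = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        k = int(sel.sum())
        if k < min_pairs:
            dropped += 1
            continue
        mean_r2 = float(r2[sel].mean())
        r2_adj = mean_r2 - 1.0 / n
        mid = 0.5 * (lo + hi)
        d_morgan = mid * cm_per_mb * 1e-8  # bp -> Morgan under linear map
        if map_function == "haldane":
            c = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        else:
            c = d_morgan
        if r2_adj <= 0:
            dropped += 1
            continue
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha)
        if ne <= 0:
            dropped += 1
            continue
        rows.append(NeBin(lo, hi, c, 1.0 / (2.0 * c), k, mean_r2, r2_adj, ne))
    if dropped:
        warnings.warn(f"{dropped} distance bins dropped (too few pairs or no drift signal)")
    frame = pd.DataFrame([b.__dict__ for b in rows],
                         columns=["d_lo_bp", "d_hi_bp", "c", "t", "n_pairs",
                                  "mean_r2", "r2_adj", "ne"])
    return frame.sort_values("t").reset_index(drop=True)


def historical_ne_window(
    ds: GenotypeDataset,
    min_bp: float = 5_000_000,
    max_bp: float = 25_000_000,
    alpha: float = 2.2,
    cm_per_mb: float = 1.0,
    map_function: str = "linear",
) -> NeBin:
    """Single recent-horizon Ne point estimate from one pooled distance
    window.

    All intrachromosomal pairs with distance in [min_bp, max_bp] are
    pooled, the mean r^2 is corrected by 1/n and inverted once at the
    pairs-mean recombination fraction.  Pooling before inversion avoids
    the convexity noise of inverting many small bins separately, at the
    cost of collapsing the window to one (recent) time point t = 1/(2c).
    """
    d, r2 = _intrachrom_pairs(ds, min_bp, max_bp)
    if len(d) == 0:
        raise ValueError("no intrachromosomal pairs in the requested window")
    mean_r2 = float(r2.mean())
    r2_adj = mean_r2 - 1.0 / ds.n_samples
    d_morgan = float(d.mean()) * cm_per_mb * 1e-8
    c = 0.5 * (1.0 - np.exp(-2.0 * d_morgan)) if map_function == "haldane" else d_morgan
    ne = (
        (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha) if r2_adj > 0 else float("inf")
    )
    return NeBin(min_bp, max_bp, c, 1.0 / (2.0 * c), len(d), mean_r2, r2_adj, float(ne))


def expected_sampling_r2(s: float) -> float:
    """E(r^2) from finite sampling alone under random mating
    (Waples 2006 regression coefficients)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _ne_from_r2_drift(r2_drift: float, s: float) -> float:
    if r2_drift <= 0:
        return float("inf")
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2_drift
        if disc < 0:
            return float("inf")
        return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_drift)
    disc = 0.308**2 - 2.08 * r2_drift
    if disc < 0:
        return float("inf")
    return (0.308 + np.sqrt(disc)) / (2.0 * r2_drift)


def contemporary_ne(
    ds: GenotypeDataset,
    maf_crit: float = 0.05,
    mating: str = "random",
) -> ContemporaryNeResult:
    """Waples & Do bias-corrected LD estimate of contemporary Ne from
    unlinked (different-chromosome) marker pairs.

    Markers with MAF below ``maf_crit`` are excluded.  Only the
    random-mating coefficient set is implemented.
    """
    if mating != "random":
        raise NotImplementedError("only the random-mating option is implemented")
    maf = np.nan_to_num(ds.maf(), nan=0.0)
    keep = np.flatnonzero(maf >= maf_crit)
    ds = ds.take_markers(keep)
    chrom = ds.markers["chrom"].to_numpy(dtype=object)
    if len(pd.unique(chrom)) < 2:
        raise ValueError("need markers on >= 2 chromosomes to form unlinked pairs")

    r2, n = r2_matrix(ds.calls)
    different = chrom[:, None] != chrom[None, :]
    iu = np.triu_indices(ds.n_markers, k=1)
    sel = different[iu]
    r2 = r2[iu][sel]
    n = n[iu][sel]
    ok = n >= 2
    r2, n = r2[ok], n[ok]
    if len(r2) == 0:
        raise ValueError("no informative unlinked pairs")

    # Burrows-composite small-sample convention: the per-pair correlation
    # carries an n/(n-1) factor, so its independence expectation matches
    # the 1/S + 3.19/S^2 sampling formula this estimator subtracts
    r2 = r2 * (n / (n - 1.0)) ** 2
    s = len(n) / np.sum(1.0 / n)  # harmonic mean of per-pair sample sizes
    mean_r2 = float(r2.mean())
    e_samp = expected_sampling_r2(s)
    r2_drift = mean_r2 - e_samp
    return ContemporaryNeResult(
        float(s), int(len(r2)), mean_r2, float(e_samp), float(r2_drift),
        float(_ne_from_r2_drift(r2_drift, s)),
    )
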