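"""Per-locus and summary diversity statistics: H_O, H_E, MAF, F_IS.

Expected heterozygosity uses the small-sample unbiased estimator
``2p(1-p) * 2n/(2n-1)`` by default (Nei & Roychoudhury); the uncorrected
``2p(1-p)`` is available via ``unbiased=False``.  F_IS is reported as the
mean of per-individual method-of-moments excess-homozygosity coefficients
(the PLINK ``--het`` convention):

    F_i = (O_hom_i - E_hom_i) / (L_i - E_hom_i)

with E_hom_i the sum over the individual's called loci of
``1 - 2p(1-p) * 2n/(2n-1)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass
class DiversitySummary:
    """Mean +/- sample sd across loci (h_obs, h_exp, maf) and across
    individuals (f_is)."""

    h_obs_mean: float
    h_obs_sd: float
    h_exp_mean: float
    h_exp_sd: float
    maf_mean: float
    maf_sd: float
    f_is_mean: float
    f_is_sd: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def locus_stats(ds: GenotypeDataset, unbiased: bool = True) -> pd.DataFrame:
    """Per-marker allele frequency, MAF, observed and expected
    heterozygosity and called-sample count.

    Markers with zero non-missing calls are excluded with a warning.
    """
    calls = ds.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    zero = n_called == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} markers with no calls excluded from locus stats")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called)
        h_obs = (calls == 1).sum(axis=0) / n_called
        h_exp = 2.0 * p * (1.0 - p)
        if unbiased:
            h_exp = h_exp * (2.0 * n_called) / (2.0 * n_called - 1.0)
    table = pd.DataFrame(
        {
            "id": ds.markers["id"].to_numpy(),
            "p": p,
            "maf": np.minimum(p, 1.0 - p),
            "h_obs": h_obs,
            "h_exp": h_exp,
            "n_called": n_called,
        }
    )
    return table.loc[~zero].reset_index(drop=True)


def individual_fis(ds: GenotypeDataset, unbiased: bool = True) -> pd.DataFrame:
    """Per-individual excess-homozygosity inbreeding coefficient.

    Degenerate individuals (L_i == E_hom_i, e.g. nothing called) get NaN.
    """
    stats = locus_stats(ds, unbiased=unbiased)
    keep = ds.markers["id"].isin(stats["id"]).to_numpy()
    calls = ds.calls[:, keep]
    # expected homozygote probability per locus, under HWE at the sample p
    e_hom_locus = 1.0 - stats["h_exp"].to_numpy()

    called = calls != MISSING
    L = called.sum(axis=1).astype(float)
    o_hom = (called & (calls != 1)).sum(axis=1).astype(float)
    e_hom = called @ e_hom_locus
    denom = L - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    return pd.DataFrame(
        {
            "fid": ds.samples["fid"],
            "iid": ds.samples["iid"],
            "n_called": L.astype(int),
            "o_hom": o_hom.astype(int),
            "e_hom": e_hom,
            "f": f,
        }
    )


def diversity_summary(ds: GenotypeDataset, unbiased: bool = True) -> DiversitySummary:
    """Means and sample standard deviations of the per-locus statistics,
    plus mean/sd of per-individual F."""
    stats = locus_stats(ds, unbiased=unbiased)
    if len(stats) < 2:
        raise ValueError("diversity summary needs at least 2 informative loci")
    fis = individual_fis(ds, unbiased=unbiased)["f"].dropna()

    def mean_sd(x) -> tuple[float, float]:
        x = np.asarray(x, dtype=float)
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    ho = mean_sd(stats["h_obs"])
    he = mean_sd(stats["h_exp"])
    maf = mean_sd(stats["maf"])
    f = mean_sd(fis) if len(fis) else (float("nan"), float("nan"))
    return DiversitySummary(*ho, *he, *maf, *f)
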