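"""Core genotype container shared by every pipeline stage.

Genotypes are stored as an ``int8`` matrix of allele-B dosages:
``0`` = homozygous for allele A, ``1`` = heterozygous, ``2`` = homozygous
for allele B, ``MISSING`` (= -1) = no call.  Which allele plays the role of
"A" is an arbitrary per-marker orientation (first allele encountered in the
input file); every downstream statistic is a function of allele frequency
and heterozygosity only and is therefore orientation-invariant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: columns of the sample table, in PLINK FAM order plus the group label
SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype", "group"]
#: columns of the marker table, in PLINK BIM order
MARKER_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]


@dataclass
class GenotypeDataset:
    """Individuals x biallelic markers with map positions.

    Parameters
    ----------
    samples
        One row per individual with columns :data:`SAMPLE_COLUMNS`.
        ``group`` is the population/breed label driving all per-group
        operations; by default it mirrors the family id.
    markers
        One row per marker with columns :data:`MARKER_COLUMNS`; positions
        are 1-based base pairs as in MAP/BIM files, chromosome labels are
        kept as text ("1".."26", "0", "X", ...).
    calls
        ``(n_samples, n_markers)`` int8 matrix of allele-B dosages with
        :data:`MISSING` for no-calls.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if self.markers["id"].duplicated().any():
            dup = self.markers.loc[self.markers["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        key = self.samples["fid"].astype(str) + "\t" + self.samples["iid"].astype(str)
        if key.duplicated().any():
            raise ValueError("duplicate (family_id, individual_id) pair")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def sample_ids(self) -> pd.Series:
        """``fid_iid`` composite identifiers (unique)."""
        return self.samples["fid"].astype(str) + "_" + self.samples["iid"].astype(str)

    # ------------------------------------------------------------------
    def take_samples(self, index) -> "GenotypeDataset":
        """Subset to samples at positional ``index`` (order preserved)."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.iloc[index], self.markers.copy(), self.calls[index, :]
        )

    def take_markers(self, index) -> "GenotypeDataset":
        """Subset to markers at positional ``index`` (order preserved)."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.copy(), self.markers.iloc[index], self.calls[:, index]
        )

    def sort_markers(self) -> "GenotypeDataset":
        """Order markers by (chromosome, position); chromosomes numerically
        where possible, non-numeric labels after, alphabetically."""
        chrom = self.markers["chrom"].astype(str)
        num = pd.to_numeric(chrom, errors="coerce")
        order = np.lexsort(
            (self.markers["pos"].to_numpy(), chrom.to_numpy(), num.fillna(np.inf).to_numpy())
        )
        return self.take_markers(order)

    def is_position_sorted(self) -> bool:
        """True if positions are non-decreasing within each chromosome block."""
        chrom = self.markers["chrom"].to_numpy(dtype=object)
        pos = self.markers["pos"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        return bool(np.all(pos[1:][same] >= pos[:-1][same]))

    # ------------------------------------------------------------------
    def allele_b_frequency(self) -> np.ndarray:
        """Per-marker frequency of allele B among non-missing calls
        (NaN where nothing is called)."""
        calls = self.calls
        called = calls != MISSING
        n_called = called.sum(axis=0)
        dosage = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dosage / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency."""
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)

    def equals(self, other: "GenotypeDataset") -> bool:
        """Code-level equality of samples, markers and calls (cM positions
        compared numerically; everything else as text)."""
        text_marker_cols = ["chrom", "id", "pos", "a1", "a2"]
        return (
            self.samples[SAMPLE_COLUMNS].astype(str).equals(other.samples[SAMPLE_COLUMNS].astype(str))
            and self.markers[text_marker_cols].astype(str).equals(other.markers[text_marker_cols].astype(str))
            and np.allclose(self.markers["cm"].astype(float), other.markers["cm"].astype(float))
            and np.array_equal(self.calls, other.calls)
        )

    def canonicalize_alleles(self) -> "GenotypeDataset":
        """Flip markers into file-order canonical orientation: allele A
        becomes the first allele that a PED reader would encounter (the
        allele of the first non-missing call).  Markers whose first
        non-missing call is homozygous for allele B get codes 0 <-> 2 and
        a1/a2 swapped.  PED text cannot store orientation, so only
        canonical datasets round-trip through PED/MAP code-for-code;
        BED/BIM stores alleles explicitly and always round-trips.
        """
        calls = self.calls.copy()
        markers = self.markers.copy()
        called = calls != MISSING
        any_called = called.any(axis=0)
        first = np.where(any_called, called.argmax(axis=0), 0)
        first_code = calls[first, np.arange(self.n_markers)]
        flip = any_called & (first_code == 2)
        if flip.any():
            sub = calls[:, flip]
            sub[sub != MISSING] = 2 - sub[sub != MISSING]
            calls[:, flip] = sub
            a1 = markers["a1"].to_numpy(dtype=object)
            a2 = markers["a2"].to_numpy(dtype=object)
            a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
            markers["a1"], markers["a2"] = a1, a2
        return GenotypeDataset(self.samples.copy(), markers, calls)


def make_sample_table(fids, iids, groups=None, **extra) -> pd.DataFrame:
    """Build a sample table from parallel id sequences (helper for
    generators and tests)."""
    fids = list(map(str, fids))
    iids = list(map(str, iids))
    table = pd.DataFrame(
        {
            "fid": fids,
            "iid": iids,
            "father": extra.get("father", ["0"] * len(fids)),
            "mother": extra.get("mother", ["0"] * len(fids)),
            "sex": extra.get("sex", ["0"] * len(fids)),
            "phenotype": extra.get("phenotype", ["-9"] * len(fids)),
        }
    )
    table["group"] = list(map(str, groups)) if groups is not None else table["fid"]
    return table


def make_marker_table(ids, chroms, positions, a1=None, a2=None, cm=None) -> pd.DataFrame:
    """Build a marker table from parallel sequences (helper for generators
    and tests)."""
    n = len(ids)
    return pd.DataFrame(
        {
            "chrom": list(map(str, chroms)),
            "id": list(map(str, ids)),
            "cm": cm if cm is not None else [0.0] * n,
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": a1 if a1 is not None else ["A"] * n,
            "a2": a2 if a2 is not None else ["G"] * n,
        }
    )
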