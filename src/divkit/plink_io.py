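"""PLINK 1.x text (PED/MAP) and binary (BED/BIM/FAM) input/output, plus the
dataset merge and per-group subsampling used to assemble multi-breed panels.

Allele orientation follows PLINK 1.x text-file behaviour: for each marker,
allele A is the first non-missing allele encountered in file order.  The
resulting 0/2 orientation is arbitrary and documented as such; every
downstream statistic is orientation-invariant.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, make_marker_table

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

#: 2-bit PLINK BED value -> internal dosage code
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
#: internal dosage code (indexed by code+1 so MISSING=-1 maps to slot 0) -> 2-bit value
_BED_ENCODE = np.array([1, 0, 2, 3], dtype=np.uint8)


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK file content."""


# ----------------------------------------------------------------------
# PED / MAP
# ----------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    """Read a 4-column MAP file into a marker table (alleles unset)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise PlinkFormatError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            rows.append((fields[0], fields[1], float(fields[2]), int(fields[3])))
    table = pd.DataFrame(rows, columns=["chrom", "id", "cm", "pos"])
    table["a1"] = "0"
    table["a2"] = "0"
    return table


def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read a PED/MAP pair.

    Allele A per marker is the first non-missing allele encountered in file
    order; "0" alleles are missing calls.  Raises
    :class:`PlinkFormatError` for ragged PED rows or a PED/MAP marker-count
    mismatch, naming the offending line.
    """
    markers = read_map(map_path)
    n_markers = len(markers)
    a1 = np.array(["0"] * n_markers, dtype=object)
    a2 = np.array(["0"] * n_markers, dtype=object)

    sample_rows = []
    call_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} "
                    f"columns for {n_markers} markers, got {len(fields)}"
                )
            sample_rows.append(fields[:6])
            alleles = np.array(fields[6:], dtype=object).reshape(n_markers, 2)
            codes = np.empty(n_markers, dtype=np.int8)
            for m in range(n_markers):
                x, y = alleles[m]
                if x == "0" or y == "0":
                    codes[m] = MISSING
                    continue
                for al in (x, y):
                    if a1[m] == "0":
                        a1[m] = al
                    elif a2[m] == "0" and al != a1[m]:
                        a2[m] = al
                dose = 0
                for al in (x, y):
                    if al == a1[m]:
                        pass
                    elif al == a2[m]:
                        dose += 1
                    else:
                        raise PlinkFormatError(
                            f"{ped_path}: line {lineno}: marker "
                            f"{markers['id'].iloc[m]!r} has >2 alleles"
                        )
                codes[m] = dose
            call_rows.append(codes)

    samples = pd.DataFrame(
        sample_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    samples["group"] = samples["fid"]
    markers["a1"] = a1
    markers["a2"] = a2
    calls = (
        np.vstack(call_rows) if call_rows else np.empty((0, n_markers), dtype=np.int8)
    )
    return GenotypeDataset(samples, markers, calls)


def write_ped_map(ds: GenotypeDataset, prefix) -> tuple[Path, Path]:
    """Write ``prefix.ped`` and ``prefix.map``; MISSING becomes "0 0"."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for row in ds.markers.itertuples(index=False):
            cm = int(row.cm) if float(row.cm) == int(row.cm) else row.cm
            fh.write(f"{row.chrom}\t{row.id}\t{cm}\t{row.pos}\n")

    # allele pair strings per (code+1): missing, hom-A, het, hom-B
    pair_for = np.empty((ds.n_markers, 4), dtype=object)
    a1 = ds.markers["a1"].to_numpy(dtype=object)
    a2 = ds.markers["a2"].to_numpy(dtype=object)
    pair_for[:, 0] = "0 0"
    pair_for[:, 1] = [f"{x} {x}" for x in a1]
    pair_for[:, 2] = [f"{x} {y}" for x, y in zip(a1, a2)]
    pair_for[:, 3] = [f"{y} {y}" for y in a2]

    with open(ped_path, "w") as fh:
        for i, row in enumerate(ds.samples.itertuples(index=False)):
            lead = f"{row.fid} {row.iid} {row.father} {row.mother} {row.sex} {row.phenotype}"
            genos = pair_for[np.arange(ds.n_markers), ds.calls[i] + 1]
            tail = " " + " ".join(genos) if ds.n_markers else ""
            fh.write(lead + tail + "\n")
    return ped_path, map_path


# ----------------------------------------------------------------------
# BED / BIM / FAM
# ----------------------------------------------------------------------

def read_bed(prefix) -> GenotypeDataset:
    """Read a BED/BIM/FAM triple (SNP-major only).

    Bit decoding per genotype: 00 -> hom allele A, 10 -> het,
    11 -> hom allele B, 01 -> missing.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    fam["group"] = fam["fid"]
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n_samples, n_markers = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (not a PLINK 1 BED file)")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: individual-major mode (0x00) is not supported; "
            "re-export in SNP-major order"
        )
    bytes_per_marker = (n_samples + 3) // 4
    payload = raw[3:]
    if len(payload) != bytes_per_marker * n_markers:
        raise PlinkFormatError(
            f"{prefix}.bed: payload has {len(payload)} bytes, expected "
            f"{bytes_per_marker * n_markers} for {n_samples} samples x {n_markers} markers"
        )
    blocks = payload.reshape(n_markers, bytes_per_marker)
    # unpack 2-bit fields, sample index increasing from the LSB of each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(n_markers, -1)[:, :n_samples]]
    return GenotypeDataset(fam, bim, codes.T)


def write_bed(ds: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write a SNP-major BED/BIM/FAM triple, bit-exact per PLINK 1.9."""
    prefix = Path(prefix)
    fam_path = prefix.with_suffix(".fam")
    bim_path = prefix.with_suffix(".bim")
    bed_path = prefix.with_suffix(".bed")
    ds.samples[["fid", "iid", "father", "mother", "sex", "phenotype"]].to_csv(
        fam_path, sep="\t", header=False, index=False
    )
    bim = ds.markers.copy()
    bim["cm"] = [int(c) if float(c) == int(c) else c for c in bim["cm"]]
    bim[["chrom", "id", "cm", "pos", "a1", "a2"]].to_csv(
        bim_path, sep="\t", header=False, index=False
    )

    n_samples, n_markers = ds.shape
    bytes_per_marker = (n_samples + 3) // 4
    two_bit = _BED_ENCODE[(ds.calls.T + 1)]  # (n_markers, n_samples)
    padded = np.zeros((n_markers, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n_samples] = two_bit
    groups = padded.reshape(n_markers, bytes_per_marker, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (groups << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


def read_any(prefix) -> GenotypeDataset:
    """Read ``prefix`` as BED/BIM/FAM if present, else PED/MAP."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped found")


# ----------------------------------------------------------------------
# merge / subsample
# ----------------------------------------------------------------------

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def merge_datasets(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Concatenate the samples of two datasets on the intersection of their
    marker panels.

    Allele coding is reconciled marker by marker: if *b* carries the same
    two alleles with A/B swapped, its codes are flipped (0 <-> 2).  Markers
    with irreconcilable allele pairs — including strand-ambiguous A/T and
    C/G conflicts — are excluded and counted in the log.
    """
    key_a = set(a.samples["fid"].astype(str) + "\t" + a.samples["iid"].astype(str))
    key_b = set(b.samples["fid"].astype(str) + "\t" + b.samples["iid"].astype(str))
    if key_a & key_b:
        raise ValueError(f"duplicate sample ids across datasets: {sorted(key_a & key_b)[:5]}")

    idx_b = {mid: j for j, mid in enumerate(b.markers["id"])}
    keep_a, keep_b, flip, dropped = [], [], [], 0
    for i, mid in enumerate(a.markers["id"]):
        j = idx_b.get(mid)
        if j is None:
            continue
        a1a, a2a = a.markers["a1"].iloc[i], a.markers["a2"].iloc[i]
        a1b, a2b = b.markers["a1"].iloc[j], b.markers["a2"].iloc[j]
        set_a = {x for x in (a1a, a2a) if x != "0"}
        set_b = {x for x in (a1b, a2b) if x != "0"}
        if set_b <= set_a or set_a <= set_b:
            keep_a.append(i)
            keep_b.append(j)
            flip.append(a1b != "0" and a1b == a2a)
        else:
            dropped += 1
    if dropped:
        logger.warning("merge: %d markers dropped for irreconcilable alleles", dropped)
    if not keep_a:
        warnings.warn("merge produced an empty marker intersection")

    calls_b = b.calls[:, keep_b].copy()
    flip = np.asarray(flip, dtype=bool)
    if flip.any():
        sub = calls_b[:, flip]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        calls_b[:, flip] = sub
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    calls = np.vstack([a.calls[:, keep_a], calls_b])
    return GenotypeDataset(samples, a.markers.iloc[keep_a], calls)


def subsample_per_group(ds: GenotypeDataset, max_n: int, seed: int) -> GenotypeDataset:
    """Retain at most ``max_n`` individuals per group, chosen uniformly at
    random; deterministic given ``seed``.  Marker content is unchanged."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for _, idx in ds.samples.groupby("group", sort=True).groups.items():
        idx = np.asarray(idx)
        if len(idx) > max_n:
            idx = np.sort(rng.choice(idx, size=max_n, replace=False))
        keep.extend(idx.tolist())
    return ds.take_samples(np.sort(np.asarray(keep)))
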