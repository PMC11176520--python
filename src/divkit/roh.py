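"""Runs-of-homozygosity detection (consecutive-runs method), length
classes, per-individual / per-chromosome summaries and the genomic
inbreeding coefficient F_ROH.

A run is a stretch of consecutive homozygous, non-missing markers in one
individual on one chromosome in which no inter-marker gap exceeds
``max_gap_bp``.  It is emitted if it contains at least ``min_snp`` markers
and spans at least ``min_length_bp`` (length = end - start, the convention
under which a run from 47,169,096 to 49,619,573 bp is 2,450,477 bp long).
By default a run may mix the two homozygous genotypes: "opposite
genotypes" means heterozygotes only, as in the consecutive method of
detectRUNS; ``same_allele=True`` additionally breaks runs at transitions
between the two homozygote classes.

``max_opposite``/``max_missing`` allowances above zero use a greedy scan
(the run closes when the allowance is exceeded); at the default 0/0 this
is identical to enumerating maximal qualifying runs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

#: length-class edges in Mb; classes are left-closed, right-open
LENGTH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0, np.inf)
LENGTH_CLASS_LABELS = ("1-2", "2-4", "4-8", "8-16", ">16")

#: total sheep autosomal genome length used for F_ROH (~2.4 Gb)
DEFAULT_GENOME_LENGTH_BP = 2_400_000_000


@dataclass
class ROHParams:
    min_snp: int = 15
    max_opposite: int = 0
    max_missing: int = 0
    max_gap_bp: int = 250_000
    min_length_bp: int = 1_000_000
    same_allele: bool = False

    def __post_init__(self) -> None:
        if min(self.min_snp, self.max_opposite, self.max_missing, self.max_gap_bp) < 0:
            raise ValueError("ROH parameters must be non-negative")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def _scan_individual(calls, pos, params: ROHParams):
    """Yield (start_idx, end_idx, n_snp) runs for one individual on one
    position-sorted chromosome block."""
    n = len(pos)
    runs = []
    start = None  # index of first marker of current candidate
    prev_hom = None  # last homozygote code, for same_allele mode
    n_opp = n_miss = 0
    count = 0

    def close(end_idx):
        nonlocal start, n_opp, n_miss, count
        if start is not None and count > 0:
            runs.append((start, end_idx, count))
        start, n_opp, n_miss, count = None, 0, 0, 0

    last_kept = None  # index of last marker inside the current run
    for i in range(n):
        g = calls[i]
        if start is not None and last_kept is not None and pos[i] - pos[last_kept] > params.max_gap_bp:
            close(last_kept)
            prev_hom = None
        if g == MISSING:
            n_miss += 1 if start is not None else 0
            if start is not None and n_miss > params.max_missing:
                close(last_kept)
                prev_hom = None
            continue
        if g == 1 or (
            params.same_allele and start is not None and prev_hom is not None and g != prev_hom
        ):
            if start is not None:
                n_opp += 1
                if n_opp > params.max_opposite:
                    close(last_kept)
            prev_hom = g if g != 1 else None
            if g != 1 and start is None:
                start, count, last_kept = i, 1, i
            continue
        # homozygous marker extends (or opens) the run
        if start is None:
            start, n_opp, n_miss, count = i, 0, 0, 0
        count += 1
        last_kept = i
        prev_hom = g
    close(last_kept)
    return runs


def detect_roh(ds: GenotypeDataset, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH in every individual of a position-sorted autosomal
    dataset.  Raises if markers are not position-sorted."""
    params = params or ROHParams()
    if not ds.is_position_sorted():
        raise ValueError("markers must be position-sorted within chromosomes")
    segments: list[ROHSegment] = []
    ids = ds.sample_ids().to_numpy()
    chrom = ds.markers["chrom"].to_numpy(dtype=object)
    pos = ds.markers["pos"].to_numpy()
    # contiguous chromosome blocks in file order
    block_starts = [0] + [i for i in range(1, len(chrom)) if chrom[i] != chrom[i - 1]] + [len(chrom)]
    for b in range(len(block_starts) - 1):
        lo, hi = block_starts[b], block_starts[b + 1]
        cpos = pos[lo:hi]
        for s in range(ds.n_samples):
            for i0, i1, n_snp in _scan_individual(ds.calls[s, lo:hi], cpos, params):
                start_bp, end_bp = int(cpos[i0]), int(cpos[i1])
                if n_snp >= params.min_snp and end_bp - start_bp >= params.min_length_bp:
                    segments.append(
                        ROHSegment(ids[s], str(chrom[lo]), start_bp, end_bp, n_snp)
                    )
    return segments


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segments as a tidy table (individual, chrom, start, end, n_snp,
    length_bp, length_mb)."""
    return pd.DataFrame(
        [
            {
                "individual": s.individual,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snp": s.n_snp,
                "length_bp": s.length_bp,
                "length_mb": s.length_mb,
            }
            for s in segments
        ],
        columns=["individual", "chrom", "start_bp", "end_bp", "n_snp", "length_bp", "length_mb"],
    )


def classify_lengths(segments: list[ROHSegment]) -> pd.DataFrame:
    """Count segments per length class (left-closed bins 1-2, 2-4, 4-8,
    8-16, >16 Mb) with percentages of the total."""
    lengths = np.array([s.length_mb for s in segments], dtype=float)
    counts = []
    for lo, hi in zip(LENGTH_CLASS_EDGES_MB[:-1], LENGTH_CLASS_EDGES_MB[1:]):
        counts.append(int(((lengths >= lo) & (lengths < hi)).sum()))
    total = len(segments)
    return pd.DataFrame(
        {
            "class_mb": LENGTH_CLASS_LABELS,
            "count": counts,
            "percent": [100.0 * c / total if total else 0.0 for c in counts],
        }
    )


@dataclass
class ROHSummary:
    n_roh_mean: float          # mean ROH count per individual
    n_roh_sd: float
    l_roh_mean_mb: float       # mean segment length (over segments), Mb
    l_roh_sd_mb: float
    nc_roh_mean: float         # mean per-chromosome segment count
    nc_roh_sd: float
    lc_roh_mean_mb: float      # mean of per-chromosome mean lengths, Mb
    lc_roh_sd_mb: float
    total_segments: int
    per_individual: pd.DataFrame
    per_chromosome: pd.DataFrame
    length_classes: pd.DataFrame


def summarize_roh(
    segments: list[ROHSegment],
    individuals: list[str],
    chromosomes: list[str],
) -> ROHSummary:
    """Summaries over a fixed universe of individuals and chromosomes;
    zero-ROH individuals and empty chromosomes contribute zero counts."""
    frame = segments_frame(segments)

    per_ind = (
        frame.groupby("individual")
        .agg(n_roh=("length_mb", "size"), mean_length_mb=("length_mb", "mean"),
             total_length_bp=("length_bp", "sum"))
        .reindex([str(i) for i in individuals])
    )
    per_ind["n_roh"] = per_ind["n_roh"].astype(float).fillna(0).astype(int)
    per_ind["total_length_bp"] = (
        per_ind["total_length_bp"].astype(float).fillna(0).astype(int)
    )

    per_chrom = (
        frame.groupby("chrom")
        .agg(nc_roh=("length_mb", "size"), lc_roh_mb=("length_mb", "mean"))
        .reindex([str(c) for c in chromosomes])
    )
    per_chrom["nc_roh"] = per_chrom["nc_roh"].astype(float).fillna(0).astype(int)

    def mean_sd(x):
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        if len(x) == 0:
            return float("nan"), float("nan")
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    n_mean, n_sd = mean_sd(per_ind["n_roh"])
    l_mean, l_sd = mean_sd(frame["length_mb"])
    nc_mean, nc_sd = mean_sd(per_chrom["nc_roh"])
    lc_mean, lc_sd = mean_sd(per_chrom["lc_roh_mb"])
    return ROHSummary(
        n_mean, n_sd, l_mean, l_sd, nc_mean, nc_sd, lc_mean, lc_sd,
        len(segments), per_ind.reset_index(), per_chrom.reset_index(),
        classify_lengths(segments),
    )


def froh(
    segments: list[ROHSegment],
    individual: str,
    genome_length_bp: int = DEFAULT_GENOME_LENGTH_BP,
) -> float:
    """Genomic inbreeding coefficient: summed ROH length of one individual
    divided by the total autosomal genome length."""
    mine = sorted(
        (s for s in segments if s.individual == str(individual)),
        key=lambda s: (s.chrom, s.start_bp),
    )
    for a, b in zip(mine, mine[1:]):
        if a.chrom == b.chrom and b.start_bp <= a.end_bp:
            raise ValueError(f"overlapping segments for individual {individual!r}")
    return sum(s.length_bp for s in mine) / genome_length_bp


def froh_table(
    segments: list[ROHSegment],
    individuals: list[str],
    genome_length_bp: int = DEFAULT_GENOME_LENGTH_BP,
) -> pd.DataFrame:
    """Per-individual F_ROH over a fixed individual universe (zero-ROH
    individuals get 0)."""
    return pd.DataFrame(
        {
            "individual": [str(i) for i in individuals],
            "froh": [froh(segments, i, genome_length_bp) for i in individuals],
        }
    )


def segments_to_bed(segments: list[ROHSegment]) -> str:
    """Serialize segments as BED text (0-based half-open: start-1, end)."""
    lines = [
        f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.individual}\t{s.n_snp}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
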