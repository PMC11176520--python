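"""ROH islands: per-SNP incidence in runs of homozygosity, z-scores, and
the top-percentile scan that turns flagged markers into genomic intervals.

A marker is "in" an individual's ROH when its position lies inside one of
that individual's segments (closed interval).  The z-score standardizes
marker incidence over all markers; flagging is by incidence rank — the
top ``top_fraction`` of markers (ceil, ties included) — which is
equivalent to a smallest-p rule.  Flagged markers closer than
``merge_gap_bp`` on the same chromosome merge into one island spanning
first to last flagged member.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import GenotypeDataset
from .roh import ROHSegment


@dataclass(frozen=True)
class IslandInterval:
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int
    member_ids: tuple[str, ...]

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def snp_incidence(
    segments: list[ROHSegment],
    markers: pd.DataFrame,
    n_individuals: int,
) -> pd.DataFrame:
    """Per-marker count/proportion of individuals whose ROH covers it,
    with z-scores and upper-tail normal p-values.

    If every marker has the same incidence (sd = 0) the z/p columns are
    NaN and the table is flagged degenerate via a warning.
    """
    pos = markers["pos"].to_numpy()
    chrom = markers["chrom"].to_numpy(dtype=object)
    count = np.zeros(len(markers), dtype=np.int64)
    by_ind_chrom: dict[tuple[str, str], list[ROHSegment]] = {}
    for s in segments:
        by_ind_chrom.setdefault((s.individual, s.chrom), []).append(s)
    for c in np.unique(chrom):
        sel = chrom == c
        cpos = pos[sel]
        acc = np.zeros(len(cpos), dtype=np.int64)
        for (ind, sc), segs in by_ind_chrom.items():
            if sc != c:
                continue
            covered = np.zeros(len(cpos), dtype=bool)
            for s in segs:
                covered |= (cpos >= s.start_bp) & (cpos <= s.end_bp)
            acc += covered
        count[sel] = acc

    sd = count.std()
    if sd == 0:
        warnings.warn("degenerate incidence table: all markers have equal incidence")
        z = np.full(len(markers), np.nan)
    else:
        z = (count - count.mean()) / sd
    return pd.DataFrame(
        {
            "id": markers["id"].to_numpy(),
            "chrom": chrom,
            "pos": pos,
            "count": count,
            "proportion": count / n_individuals,
            "z": z,
            "p": sps.norm.sf(z),
        }
    )


def island_scan(
    table: pd.DataFrame,
    top_fraction: float = 0.001,
    merge_gap_bp: int = 1_000_000,
) -> list[IslandInterval]:
    """Flag the top-incidence markers and merge them into islands.

    Exactly ``ceil(top_fraction * n_markers)`` markers are flagged, except
    that ties at the selection boundary are all included.  Returns an
    empty list for a degenerate (zero-variance) incidence table.
    """
    if table["z"].isna().all():
        return []
    n_flag = math.ceil(top_fraction * len(table))
    if n_flag < 1:
        return []
    counts = table["count"].to_numpy()
    cutoff = np.sort(counts)[::-1][n_flag - 1]
    flagged = table.loc[counts >= cutoff]
    if len(flagged) > n_flag:
        warnings.warn(
            f"{len(flagged) - n_flag} extra markers flagged due to ties at the boundary"
        )

    islands: list[IslandInterval] = []
    for c, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        ids = sub["id"].to_numpy(dtype=object)
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        start = 0
        for b in list(breaks) + [len(pos) - 1]:
            islands.append(
                IslandInterval(
                    str(c),
                    int(pos[start]),
                    int(pos[b]),
                    b - start + 1,
                    tuple(ids[start : b + 1]),
                )
            )
            start = b + 1
    return sorted(islands, key=lambda i: (i.chrom, i.start_bp))


def annotate_intervals(
    islands: list[IslandInterval], features: pd.DataFrame
) -> pd.DataFrame:
    """Overlap report between islands and annotation intervals.

    ``features`` needs columns chrom/start/end/name (plus optional type);
    closed intervals overlap when they share the chromosome and at least
    one base (a feature ending exactly at an island start overlaps).
    Malformed feature rows are skipped with a counted warning.
    """
    rows, skipped = [], 0
    for _, f in features.iterrows():
        try:
            fc, fs, fe = str(f["chrom"]), int(f["start"]), int(f["end"])
            name = str(f["name"])
        except (KeyError, TypeError, ValueError):
            skipped += 1
            continue
        if fs > fe:
            skipped += 1
            continue
        for isl in islands:
            if isl.chrom == fc and fs <= isl.end_bp and fe >= isl.start_bp:
                rows.append(
                    {
                        "island_chrom": isl.chrom,
                        "island_start": isl.start_bp,
                        "island_end": isl.end_bp,
                        "feature": name,
                        "feature_type": str(f.get("type", "")),
                        "feature_start": fs,
                        "feature_end": fe,
                    }
                )
    if skipped:
        warnings.warn(f"{skipped} malformed feature rows skipped")
    return pd.DataFrame(
        rows,
        columns=[
            "island_chrom", "island_start", "island_end",
            "feature", "feature_type", "feature_start", "feature_end",
        ],
    )


def read_bed_features(path) -> pd.DataFrame:
    """Read BED annotation intervals into the feature-table schema
    (BED is 0-based half-open; converted to 1-based closed)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            name = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}-{fields[2]}"
            rows.append(
                {"chrom": fields[0], "start": int(fields[1]) + 1, "end": int(fields[2]),
                 "name": name, "type": "bed"}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "type"])


def read_gff_features(path) -> pd.DataFrame:
    """Read GFF3 intervals (1-based closed already) into the feature-table
    schema; the Name/ID attribute becomes the feature name."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID", fields[2]))
            rows.append(
                {"chrom": fields[0], "start": int(fields[3]), "end": int(fields[4]),
                 "name": name, "type": fields[2]}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "type"])


def islands_to_bed(islands: list[IslandInterval]) -> str:
    """Islands as BED text (0-based half-open)."""
    lines = [
        f"{i.chrom}\t{i.start_bp - 1}\t{i.end_bp}\tisland_{k}\t{i.n_snp}"
        for k, i in enumerate(islands, 1)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
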