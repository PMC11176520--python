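"""Quality-control cascade for SNP-array panels.

Stage order mirrors PLINK 1.9: autosome restriction, then individual call
rate (``--mind``), then per-SNP call rate (``--geno``), then minor allele
frequency (``--maf``), then optional windowed LD pruning
(``--indep-pairwise``).  Allele frequencies for the MAF stage are
recomputed after individual removal.  Every stage logs removed/retained
counts so the report telescopes.

Defaults are the thresholds routinely used for Illumina OvineSNP50 panels:
MAF >= 0.05, SNP call rate >= 0.95, individual call rate >= 0.99,
26 sheep autosomes, pruning at r^2 > 0.2 in 50-SNP windows stepping by 10.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import MISSING, GenotypeDataset
from .ld import r2_matrix


@dataclass
class QCConfig:
    maf_min: float = 0.05
    snp_call_min: float = 0.95
    ind_call_min: float = 0.99
    autosome_count: int = 26
    prune_r2: float = 0.2
    prune_window: int = 50
    prune_step: int = 10
    prune_enabled: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_min", "ind_call_min", "prune_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.prune_window >= self.prune_step >= 1:
            raise ValueError("need prune_window >= prune_step >= 1")


@dataclass
class QCStage:
    name: str
    markers_in: int
    markers_removed: int
    samples_in: int
    samples_removed: int

    @property
    def markers_out(self) -> int:
        return self.markers_in - self.markers_removed

    @property
    def samples_out(self) -> int:
        return self.samples_in - self.samples_removed


@dataclass
class QCReport:
    stages: list[QCStage] = field(default_factory=list)

    def add(self, name, before: GenotypeDataset, after: GenotypeDataset) -> None:
        self.stages.append(
            QCStage(
                name,
                before.n_markers,
                before.n_markers - after.n_markers,
                before.n_samples,
                before.n_samples - after.n_samples,
            )
        )

    def to_dict(self) -> dict:
        out = []
        for s in self.stages:
            d = asdict(s)
            d["markers_out"] = s.markers_out
            d["samples_out"] = s.samples_out
            out.append(d)
        return {"stages": out}

    def __str__(self) -> str:
        lines = [f"{'stage':<22}{'markers':>10}{'-removed':>10}{'samples':>9}{'-removed':>10}"]
        for s in self.stages:
            lines.append(
                f"{s.name:<22}{s.markers_in:>10}{s.markers_removed:>10}"
                f"{s.samples_in:>9}{s.samples_removed:>10}"
            )
        return "\n".join(lines)


# ----------------------------------------------------------------------

def filter_autosomes(ds: GenotypeDataset, n_autosomes: int = 26) -> GenotypeDataset:
    """Keep markers whose chromosome label is "1".."n_autosomes"; labels
    "0", sex chromosomes and anything non-numeric are removed."""
    allowed = {str(i) for i in range(1, n_autosomes + 1)}
    keep = ds.markers["chrom"].astype(str).isin(allowed).to_numpy()
    if not keep.any():
        warnings.warn("autosome filter removed every marker")
    return ds.take_markers(np.flatnonzero(keep))


def filter_individual_callrate(ds: GenotypeDataset, threshold: float = 0.99) -> GenotypeDataset:
    """Keep individuals with (non-missing calls / total markers) >= threshold."""
    if ds.n_markers == 0:
        return ds
    rate = (ds.calls != MISSING).mean(axis=1)
    return ds.take_samples(np.flatnonzero(rate >= threshold))


def filter_snp_callrate(ds: GenotypeDataset, threshold: float = 0.95) -> GenotypeDataset:
    """Keep markers whose fraction of non-missing calls is >= threshold."""
    if ds.n_samples == 0:
        return ds
    rate = (ds.calls != MISSING).mean(axis=0)
    return ds.take_markers(np.flatnonzero(rate >= threshold))


def filter_maf(ds: GenotypeDataset, threshold: float = 0.05) -> GenotypeDataset:
    """Keep markers with minor allele frequency >= threshold (frequencies
    from non-missing calls of the currently retained samples)."""
    maf = ds.maf()
    keep = np.nan_to_num(maf, nan=-1.0) >= threshold
    return ds.take_markers(np.flatnonzero(keep))


def ld_prune(
    ds: GenotypeDataset,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 10,
) -> list[str]:
    """Greedy windowed LD pruning; returns the retained marker ids.

    Within each window of ``window`` currently-retained markers (windows
    slide by ``step`` along each chromosome) the highest-r^2 violating pair
    is resolved by dropping its lower-MAF member (tie: the later-positioned
    marker).  Passes repeat until no within-window pair exceeds ``r2_max``.
    """
    if not ds.is_position_sorted():
        ds = ds.sort_markers()
    maf = np.nan_to_num(ds.maf(), nan=0.0)
    retained = np.ones(ds.n_markers, dtype=bool)
    chrom = ds.markers["chrom"].to_numpy(dtype=object)

    changed = True
    while changed:
        changed = False
        for c in np.unique(chrom):
            cidx = np.flatnonzero((chrom == c) & retained)
            start = 0
            while start < len(cidx):
                win = cidx[start : start + window]
                win = win[retained[win]]  # may have been pruned by earlier window
                if len(win) >= 2:
                    r2, _ = r2_matrix(ds.calls[:, win])
                    np.fill_diagonal(r2, 0.0)
                    r2 = np.triu(r2)
                    alive = np.ones(len(win), dtype=bool)
                    while True:
                        masked = np.where(np.outer(alive, alive), r2, 0.0)
                        i, j = np.unravel_index(np.argmax(masked), masked.shape)
                        if masked[i, j] <= r2_max:
                            break
                        mi, mj = win[i], win[j]
                        if maf[mi] < maf[mj]:
                            drop = i
                        elif maf[mj] < maf[mi]:
                            drop = j
                        else:  # tie: drop the later-positioned marker
                            drop = j
                        alive[drop] = False
                        retained[win[drop]] = False
                        changed = True
                start += step
    return ds.markers["id"].iloc[np.flatnonzero(retained)].tolist()


def run_qc(ds: GenotypeDataset, config: QCConfig | None = None) -> tuple[GenotypeDataset, QCReport]:
    """Apply the full cascade in fixed order and return the filtered
    dataset together with a telescoping per-stage report."""
    config = config or QCConfig()
    report = QCReport()

    out = filter_autosomes(ds, config.autosome_count)
    report.add("autosomes", ds, out)

    prev, out = out, filter_individual_callrate(out, config.ind_call_min)
    report.add("individual_callrate", prev, out)

    prev, out = out, filter_snp_callrate(out, config.snp_call_min)
    report.add("snp_callrate", prev, out)

    prev, out = out, filter_maf(out, config.maf_min)
    report.add("maf", prev, out)

    if config.prune_enabled:
        keep_ids = set(ld_prune(out, config.prune_r2, config.prune_window, config.prune_step))
        prev = out
        out = out.take_markers(np.flatnonzero(out.markers["id"].isin(keep_ids).to_numpy()))
        report.add("ld_prune", prev, out)

    return out, report
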