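"""One-call orchestration of the two analysis tracks.

* :func:`run_characterization` — single-population track: QC, diversity
  indices, ROH detection with length classes and F_ROH, ROH islands, and
  historical/contemporary Ne.  Emits per-stage TSV/JSON files.
* :func:`run_structure` — multi-population track: optional merge and
  per-breed subsampling, QC with LD pruning, IBS distances and classical
  MDS, pairwise Weir-Cockerham F_ST with Reynolds distances, and a
  neighbor-joining tree in Newick format.

Both are deterministic given the config seed, and log input/output
dimensions per stage so every number in the bundle is auditable.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, islands, ne, plink_io, qc, roh, structure
from .dataset import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path = Path("divkit_out")
    qc_config: qc.QCConfig = field(default_factory=qc.QCConfig)
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    island_top_fraction: float = 0.001
    island_merge_gap_bp: int = 1_000_000
    genome_length_bp: int = roh.DEFAULT_GENOME_LENGTH_BP
    ne_alpha: float = 2.2
    ne_maf_crit: float = 0.05
    subsample_max: int = 30
    seed: int = 0


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_characterization(ds: GenotypeDataset, config: PipelineConfig | None = None) -> dict:
    """Single-population characterization; returns the result bundle and
    writes TSV/JSON artifacts under ``config.out_dir``."""
    config = config or PipelineConfig()
    out = Path(config.out_dir)

    filtered, report = qc.run_qc(ds, config.qc_config)
    logger.info("QC: %d/%d markers, %d/%d samples retained",
                filtered.n_markers, ds.n_markers, filtered.n_samples, ds.n_samples)
    filtered = filtered.sort_markers()
    _write(out / "qc_report.json", json.dumps(report.to_dict(), indent=2))
    _write(out / "qc_report.txt", str(report) + "\n")

    summary = diversity.diversity_summary(filtered)
    locus = diversity.locus_stats(filtered)
    fis = diversity.individual_fis(filtered)
    _write(out / "locus_stats.tsv", locus.to_csv(sep="\t", index=False))
    _write(out / "individual_f.tsv", fis.to_csv(sep="\t", index=False))

    segments = roh.detect_roh(filtered, config.roh_params)
    individuals = filtered.sample_ids().tolist()
    chromosomes = pd.unique(filtered.markers["chrom"]).tolist()
    roh_summary = roh.summarize_roh(segments, individuals, chromosomes)
    froh = roh.froh_table(segments, individuals, config.genome_length_bp)
    _write(out / "roh_segments.tsv", roh.segments_frame(segments).to_csv(sep="\t", index=False))
    _write(out / "roh_segments.bed", roh.segments_to_bed(segments))
    _write(out / "roh_length_classes.tsv", roh_summary.length_classes.to_csv(sep="\t", index=False))
    _write(out / "froh.tsv", froh.to_csv(sep="\t", index=False))

    incidence = islands.snp_incidence(segments, filtered.markers, filtered.n_samples)
    found = islands.island_scan(
        incidence, config.island_top_fraction, config.island_merge_gap_bp
    )
    _write(out / "snp_incidence.tsv", incidence.to_csv(sep="\t", index=False))
    _write(out / "roh_islands.bed", islands.islands_to_bed(found))

    trajectory = ne.historical_ne(filtered, alpha=config.ne_alpha)
    _write(out / "ne_trajectory.tsv", trajectory.to_csv(sep="\t", index=False))
    n_chroms = filtered.markers["chrom"].nunique()
    contemporary = (
        ne.contemporary_ne(filtered, maf_crit=config.ne_maf_crit)
        if n_chroms >= 2 else None
    )

    table1 = {
        "h_obs": summary.h_obs_mean, "h_obs_sd": summary.h_obs_sd,
        "h_exp": summary.h_exp_mean, "h_exp_sd": summary.h_exp_sd,
        "f_is": summary.f_is_mean, "f_is_sd": summary.f_is_sd,
        "maf": summary.maf_mean, "maf_sd": summary.maf_sd,
        "froh": float(froh["froh"].mean()), "froh_sd": float(froh["froh"].std(ddof=1)),
        "n_roh": roh_summary.n_roh_mean, "n_roh_sd": roh_summary.n_roh_sd,
        "l_roh_mb": roh_summary.l_roh_mean_mb, "l_roh_sd_mb": roh_summary.l_roh_sd_mb,
        "ne_contemporary": contemporary.ne if contemporary else float("nan"),
        "total_roh": roh_summary.total_segments,
    }
    _write(out / "table1_style_summary.tsv",
           pd.DataFrame([table1]).to_csv(sep="\t", index=False))
    table2 = pd.DataFrame(
        [{"chrom": i.chrom, "start_bp": i.start_bp, "end_bp": i.end_bp,
          "length_bp": i.length_bp, "n_snp": i.n_snp} for i in found]
    )
    _write(out / "table2_style_islands.tsv", table2.to_csv(sep="\t", index=False))

    return {
        "qc_report": report,
        "dataset": filtered,
        "diversity": summary,
        "segments": segments,
        "roh_summary": roh_summary,
        "froh": froh,
        "incidence": incidence,
        "islands": found,
        "ne_trajectory": trajectory,
        "ne_contemporary": contemporary,
        "summary": table1,
    }


def run_structure(
    ds: GenotypeDataset,
    config: PipelineConfig | None = None,
    extra: GenotypeDataset | None = None,
) -> dict:
    """Multi-population structure track; ``extra`` is merged in first when
    given (marker intersection, allele reconciliation)."""
    config = config or PipelineConfig()
    out = Path(config.out_dir)

    if extra is not None:
        ds = plink_io.merge_datasets(ds, extra)
    ds = plink_io.subsample_per_group(ds, config.subsample_max, config.seed)

    qc_conf = config.qc_config
    if not qc_conf.prune_enabled:
        qc_conf = qc.QCConfig(**{**qc_conf.__dict__, "prune_enabled": True})
    filtered, report = qc.run_qc(ds, qc_conf)
    filtered = filtered.sort_markers()
    _write(out / "qc_report.json", json.dumps(report.to_dict(), indent=2))

    # drop groups reduced below 2 individuals
    sizes = filtered.samples.groupby("group")["iid"].size()
    small = sizes[sizes < 2].index
    if len(small):
        logger.warning("dropping groups reduced below 2 individuals: %s", list(small))
        keep = ~filtered.samples["group"].isin(small)
        filtered = filtered.take_samples(np.flatnonzero(keep.to_numpy()))

    ibs = structure.ibs_distance(filtered)
    mds = structure.classical_mds(ibs, k=2)
    coords = pd.DataFrame(
        {
            "id": mds.labels,
            "group": filtered.samples["group"].to_numpy(),
            "c1": mds.coordinates[:, 0],
            "c2": mds.coordinates[:, 1] if mds.coordinates.shape[1] > 1 else 0.0,
        }
    )
    _write(out / "ibs_distance.tsv", ibs.to_tsv())
    _write(out / "mds_coordinates.tsv", coords.to_csv(sep="\t", index=False))

    stats = structure.pairwise_fst(filtered)
    _write(out / "fst_pairs.tsv", structure.fst_long_table(stats).to_csv(sep="\t", index=False))
    reynolds = structure.fst_matrix(stats, "reynolds_d")
    _write(out / "reynolds.phylip", reynolds.to_phylip())
    tree = structure.neighbor_joining(reynolds) if len(reynolds.labels) >= 3 else None
    if tree is not None:
        _write(out / "nj_tree.nwk", structure.to_newick(tree) + "\n")

    return {
        "qc_report": report,
        "dataset": filtered,
        "ibs": ibs,
        "mds": mds,
        "mds_coordinates": coords,
        "fst": stats,
        "reynolds": reynolds,
        "tree": tree,
    }
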