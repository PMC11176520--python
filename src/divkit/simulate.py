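"""Synthetic genotype generators with known ground truth.

Three generators cover the pipeline's validation needs:

* :func:`sim_structured` — multi-population Balding-Nichols panels.  Each
  population's allele frequencies are Beta-distributed around a shared
  ancestral frequency with drift parameter F, so the parametric F_ST is
  known by construction.
* :func:`sim_wright_fisher` — forward-in-time Wright-Fisher diploids with
  recombination (Haldane map, no mutation), producing LD decay consistent
  with a known Ne for validating the LD-based Ne estimators.
* :func:`plant_roh` — overwrite a chosen region with homozygous calls in
  a chosen fraction of carriers, recording the planted segments.

Every generator is a pure function of its seed.  The default structured
panel mirrors a single-breed OvineSNP50 study at desk scale: 24
individuals, 26 autosomes of ~92 Mb, and 2,180 markers (a 50k chip
thinned twentyfold).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, make_marker_table, make_sample_table

#: per-autosome length giving a 2.4 Gb genome over 26 autosomes
DEFAULT_CHROM_LENGTH_BP = 92_307_692


@dataclass
class StructuredSimConfig:
    n_pops: int = 1
    n_per_pop: int = 24
    n_loci: int = 2180
    fst_per_pop: float | tuple[float, ...] = 0.05
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    n_autosomes: int = 26
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fs = self.fst_list()
        if not all(0.0 < f < 1.0 for f in fs):
            raise ValueError("each F must lie in (0, 1)")
        lo, hi = self.ancestral_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral frequencies must lie in (0, 1)")

    def fst_list(self) -> list[float]:
        if np.isscalar(self.fst_per_pop):
            return [float(self.fst_per_pop)] * self.n_pops
        return [float(f) for f in self.fst_per_pop]


def _uniform_marker_map(rng, n_loci, n_autosomes, chrom_length_bp) -> pd.DataFrame:
    """Markers placed uniformly at random over equal-length autosomes,
    position-sorted, with distinct positions per chromosome."""
    chroms = rng.integers(1, n_autosomes + 1, size=n_loci)
    pos = rng.integers(1, chrom_length_bp + 1, size=n_loci)
    order = np.lexsort((pos, chroms))
    chroms, pos = chroms[order], pos[order]
    # nudge duplicate positions apart so marker maps are strictly sorted
    for i in range(1, n_loci):
        if chroms[i] == chroms[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    ids = [f"snp{i + 1}" for i in range(n_loci)]
    return make_marker_table(ids, chroms.astype(str), pos)


def sim_structured(config: StructuredSimConfig) -> tuple[GenotypeDataset, dict]:
    """Balding-Nichols multi-population genotypes.

    Returns the dataset and a truth record carrying the ancestral and
    per-population allele frequencies and the population assignment.
    """
    rng = np.random.default_rng(config.seed)
    markers = _uniform_marker_map(
        rng, config.n_loci, config.n_autosomes, config.chrom_length_bp
    )
    lo, hi = config.ancestral_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)

    fs = config.fst_list()
    pop_freqs = np.empty((config.n_pops, config.n_loci))
    for k, f in enumerate(fs):
        scale = (1.0 - f) / f
        pop_freqs[k] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    pop_freqs = np.clip(pop_freqs, 1e-9, 1.0 - 1e-9)

    n_total = config.n_pops * config.n_per_pop
    calls = np.empty((n_total, config.n_loci), dtype=np.int8)
    groups = []
    for k in range(config.n_pops):
        rows = slice(k * config.n_per_pop, (k + 1) * config.n_per_pop)
        calls[rows] = rng.binomial(2, pop_freqs[k], size=(config.n_per_pop, config.n_loci))
        groups.extend([f"pop{k + 1}"] * config.n_per_pop)
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = MISSING

    samples = make_sample_table(
        groups, [f"ind{i + 1}" for i in range(n_total)], groups=groups
    )
    truth = {
        "ancestral_p": p_anc,
        "pop_freqs": pop_freqs,
        "fst_per_pop": fs,
        "groups": np.array(groups),
    }
    return GenotypeDataset(samples, markers, calls), truth


# ----------------------------------------------------------------------
# Wright-Fisher forward simulation
# ----------------------------------------------------------------------

@dataclass
class WrightFisherConfig:
    true_ne: int = 100
    n_generations: int = 200
    n_chromosomes: int = 1
    chrom_length_morgans: float = 0.5
    chrom_length_bp: int = 50_000_000
    n_loci: int = 500
    sample_n: int = 50
    init_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ne < 2:
            raise ValueError("true_ne must be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.sample_n > self.true_ne:
            raise ValueError("cannot sample more individuals than the population holds")


def _recomb_fractions(markers: pd.DataFrame, morgans_per_bp: float) -> np.ndarray:
    """Per-interval switch probabilities: Haldane within chromosomes,
    0.5 at chromosome boundaries and at the first locus."""
    chrom = markers["chrom"].to_numpy(dtype=object)
    pos = markers["pos"].to_numpy(dtype=float)
    r = np.full(len(markers), 0.5)
    same = np.flatnonzero(chrom[1:] == chrom[:-1]) + 1
    d_morgan = (pos[same] - pos[same - 1]) * morgans_per_bp
    r[same] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    return r


def sim_wright_fisher(config: WrightFisherConfig) -> tuple[GenotypeDataset, dict]:
    """Forward Wright-Fisher diploids with recombination.

    2*Ne haplotypes start at linkage equilibrium with uniform allele
    frequencies, evolve for ``n_generations`` of random mating (each
    gamete drawn from a random parent with Haldane crossovers, free
    recombination between chromosomes), then ``sample_n`` diploids are
    sampled.  If everything fixes, the simulation is retried with an
    advanced seed (warned).
    """
    rng = np.random.default_rng(config.seed)
    morgans_per_bp = config.chrom_length_morgans / config.chrom_length_bp

    for attempt in range(10):
        markers = _uniform_marker_map(
            rng, config.n_loci, config.n_chromosomes, config.chrom_length_bp
        )
        r = _recomb_fractions(markers, morgans_per_bp)
        L, ne = config.n_loci, config.true_ne
        lo, hi = config.init_freq_range
        p0 = rng.uniform(lo, hi, size=L)
        haps = (rng.random((2 * ne, L)) < p0).astype(np.int8)

        cols = np.arange(L)[None, :]
        for _ in range(config.n_generations):
            parents = rng.integers(ne, size=2 * ne)
            switch = rng.random((2 * ne, L)) < r[None, :]
            which = np.bitwise_xor.accumulate(switch, axis=1).astype(np.int64) & 1
            haps = haps[2 * parents[:, None] + which, cols]

        segregating = (haps.min(axis=0) != haps.max(axis=0))
        if segregating.any():
            break
        warnings.warn("all loci fixed; resimulating with advanced seed")
    else:
        raise RuntimeError("simulation fixed all loci in 10 attempts")

    take = rng.choice(ne, size=config.sample_n, replace=False)
    genotypes = (haps[2 * take] + haps[2 * take + 1]).astype(np.int8)
    samples = make_sample_table(
        ["wf"] * config.sample_n,
        [f"ind{i + 1}" for i in range(config.sample_n)],
    )
    truth = {
        "true_ne": config.true_ne,
        "recomb_fractions": r,
        "initial_freqs": p0,
        "segregating": segregating,
    }
    return GenotypeDataset(samples, markers, genotypes), truth


# ----------------------------------------------------------------------
# planted ROH
# ----------------------------------------------------------------------

@dataclass
class PlantedROHSpec:
    chrom: str = "1"
    start_bp: int = 1
    end_bp: int = 3_000_000
    carrier_fraction: float = 1.0
    seed: int = 0
    min_snp: int = 15
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 250_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")


def plant_roh(ds: GenotypeDataset, spec: PlantedROHSpec) -> tuple[GenotypeDataset, dict]:
    """Overwrite the spec'd region with homozygous calls in a random
    subset of carriers; returns the modified dataset and a truth record
    listing the planted segment per carrier.

    Raises if the region could never qualify as a ROH under the spec'd
    detection criteria (too few markers, too short a span, or an
    inter-marker gap above the allowance), naming the violated criterion.
    """
    chrom = ds.markers["chrom"].astype(str).to_numpy()
    pos = ds.markers["pos"].to_numpy()
    inside = np.flatnonzero(
        (chrom == str(spec.chrom)) & (pos >= spec.start_bp) & (pos <= spec.end_bp)
    )
    if len(inside) < spec.min_snp:
        raise ValueError(
            f"region holds {len(inside)} markers; minimum SNP criterion ({spec.min_snp}) unreachable"
        )
    span = int(pos[inside[-1]] - pos[inside[0]])
    if span < spec.min_length_bp:
        raise ValueError(
            f"marker span {span} bp below minimum ROH length ({spec.min_length_bp} bp)"
        )
    gaps = np.diff(pos[inside])
    if (gaps > spec.max_gap_bp).any():
        raise ValueError(
            f"largest inter-marker gap {int(gaps.max())} bp exceeds the allowance ({spec.max_gap_bp} bp)"
        )

    rng = np.random.default_rng(spec.seed)
    n_carriers = int(round(spec.carrier_fraction * ds.n_samples))
    carriers = np.sort(rng.choice(ds.n_samples, size=n_carriers, replace=False))
    calls = ds.calls.copy()
    for ind in carriers:
        calls[ind, inside] = 2 * rng.integers(0, 2, size=len(inside), dtype=np.int8)

    ids = ds.sample_ids().to_numpy()
    truth = {
        "carriers": carriers,
        "segments": [
            {
                "individual": ids[ind],
                "chrom": str(spec.chrom),
                "start_bp": int(pos[inside[0]]),
                "end_bp": int(pos[inside[-1]]),
                "n_snp": int(len(inside)),
            }
            for ind in carriers
        ],
        "marker_index": inside,
    }
    return GenotypeDataset(ds.samples.copy(), ds.markers.copy(), calls), truth
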