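# Methods and conventions

This document states every statistical convention and numerical choice
in divkit precisely enough that an independent implementation could
reproduce its output bit-for-bit.

## Genotype representation

Genotypes are dosage codes of the B allele: 0 (homozygous A), 1
(heterozygous), 2 (homozygous B), −1 (missing), stored as `int8`. When
reading PED text, the "A allele" of a marker is the first allele
encountered in file order (so PED text alone does not pin the
orientation; `GenotypeDataset.canonicalize_alleles()` produces a
file-order-canonical form, and BED/BIM/FAM round-trips are always
bit-exact since BIM stores both alleles). All statistics here are
invariant under allele relabeling (0↔2).

## Quality control

The cascade runs in a fixed order, each stage on the previous stage's
output: (1) keep autosomes 1..`autosome_count` (default 26, sheep);
(2) drop individuals with call rate < 0.99; (3) drop SNPs with call
rate < 0.95; (4) drop SNPs with MAF < 0.05; (5) optional LD pruning.
All thresholds are **inclusive** (a SNP at exactly the boundary is
kept). LD pruning is greedy and windowed: within each sliding window
(50 SNPs, step 10) every pair with r² > 0.2 is resolved by dropping the
lower-MAF member (ties: the later position); the scan repeats until a
fixpoint, guaranteeing the post-condition that no retained within-window
pair exceeds the threshold.

## Diversity

Per locus with n called individuals and B-allele frequency p:
H_O = het count / n; unbiased expected heterozygosity
H_E = 2p(1−p)·2n/(2n−1) (Nei's small-sample correction; the uncorrected
2p(1−p) is available via `unbiased=False`). Per-individual F follows
the PLINK `--het` method-of-moments convention:
F = (O_hom − E_hom)/(L − E_hom), where E_hom sums 1 − 2p(1−p)·2n/(2n−1)
over the individual's called loci. Summaries report means ± sample
standard deviations (ddof = 1) over loci (or individuals for F).

## Runs of homozygosity

Consecutive-runs detection (no sliding window): a run is a maximal
stretch of consecutive non-missing homozygous calls of one individual on
one chromosome in which no inter-marker gap exceeds `max_gap_bp`
(250 kb), reported when it has ≥ `min_snp` markers (15) and spans
≥ `min_length_bp` (1 Mb). Length is defined as `end − start` (the
convention under which a run from 47,169,096 to 49,619,573 bp is
2,450,477 bp long). `max_opposite`/`max_missing` allowances above the
0/0 default use a greedy scan (the run closes when the allowance is
exceeded); at 0/0 this is provably identical to enumerating maximal
qualifying runs, which is how the test oracle checks it. By default a
run may mix the two homozygote classes; `same_allele=True` also breaks
runs at 0↔2 transitions. Length classes are left-closed bins [1,2),
[2,4), [4,8), [8,16), [16,∞) Mb. F_ROH = Σ segment lengths / genome
length, with a 2.4 Gb sheep autosomal default.

## ROH islands

Each marker's incidence is the number of individuals whose ROH covers
its position (closed interval). Incidences are standardized to
z-scores over all markers, with upper-tail normal p-values. Flagging is
by rank: the top `ceil(0.001 · n_markers)` markers, with boundary ties
all included (warned). Flagged markers on the same chromosome closer
than 1 Mb merge into one island spanning first to last flagged member.
Annotation intervals (BED, converted to 1-based closed, or GFF3) overlap
an island when they share the chromosome and at least one base.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over jointly
called individuals, computed with a vectorized masked-matrix formula;
pairs with fewer than two joint calls or zero variance get r² = 0.

## Effective population size

**Historical** (SNeP-style): intrachromosomal pairs are binned by
physical distance over [25 kb, 25 Mb]; each bin's mean r², corrected by
−1/n for sample size, is inverted through Sved's drift expectation
E[r²] = 1/(α + 4 Ne c), giving Ne = (1/4c)(1/r²_adj − α) at time
t = 1/(2c) generations. Physical distance maps to recombination
fraction linearly at 1 cM/Mb (c = d_bp·10⁻⁸) by default; a Haldane
option exists. α = 2.2 (mutation adjustment) is the default; α = 1 is
correct for mutation-free simulations. Because per-bin inversion is
convex in r² and noisy at small c, `historical_ne_window()` pools all
pairs in one window (default 5–25 Mb) and inverts once at the
pairs-mean c — this pooled form is what the validation uses and what we
recommend for point estimates.

**Contemporary** (NeEstimator-style, Waples & Do LD method, random
mating): r² over different-chromosome (unlinked) pairs after a MAF ≥
0.05 screen. Each pair's Pearson r² is scaled by (n/(n−1))² — the
Burrows-composite small-sample convention — so that its independence
expectation matches the sampling formula being subtracted:
E(r²_sample) = 1/S + 3.19/S² for harmonic-mean sample size S ≥ 30
(0.0018 + 0.907/S + 4.44/S² below 30). The bias-corrected
r²′ = mean r² − E(r²_sample) inverts through Waples' weighted-regression
coefficients: Ne = (1/3 + √(1/9 − 2.76 r²′))/(2r²′) for S ≥ 30
(0.308 ± … variant below 30); r²′ ≤ 0 ⇒ Ne = ∞ (no drift signal
detectable).

## Population structure

IBS distance between individuals g, h is mean(|g−h|)/2 over joint
loci (equivalently 1 − shared alleles/2). Ordination uses in-house
classical (Torgerson) metric MDS — double-center −D²/2,
eigendecompose, scale by √λ — because SMACOF-style iterative MDS is
not deterministic and does not yield the eigenvalue-based
variance-explained fractions reported for SNP panels. Explained
fractions are λᵢ / Σ(positive λ).

Pairwise F_ST is the Weir–Cockerham (1984) θ for two populations:
per-locus variance components a (between populations), b (between
individuals within), c (within individuals), combined across loci as
Σa / Σ(a+b+c). Monomorphic or uncallable loci are excluded. Reynolds
distance is −ln(1 − θ) with negative θ clamped to 0. Neighbor-joining
uses scikit-bio's Saitou–Nei implementation (verified exact on additive
matrices by the test suite); negative branch lengths on non-additive
input are clamped to 0. Trees serialize to Newick.

## Synthetic data and its limits

* **Balding–Nichols** (`sim_structured`): per-population allele
  frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around a Uniform(0.1, 0.9)
  ancestral p; genotypes binomial. Parametric F_ST equals F by
  construction. Individuals are unrelated and loci independent — no LD,
  no ROH, no linked selection.
* **Wright–Fisher** (`sim_wright_fisher`): 2Ne haplotypes start at
  linkage equilibrium, evolve by random mating with Haldane
  recombination (gametes built by Bernoulli-switch cumulative XOR over
  loci; free recombination across chromosome boundaries), no mutation.
  It produces genuine drift LD on both linked and unlinked markers,
  which is what the Ne estimators need; it does not model selection,
  migration, overlapping generations or variable recombination.
* **Planted ROH** (`plant_roh`): overwrites a region with random
  homozygous calls in a chosen carrier fraction, erroring with the name
  of the violated criterion if the region could never qualify
  (too few markers, too short, too sparse). Planted runs can extend
  into flanking homozygous calls, so recovery checks use containment.

## Validation strategy

Every estimator is tested three ways: closed-form fixtures computed by
hand; independent oracles (exhaustive O(n²) maximal-run enumeration for
ROH, `numpy.corrcoef` for r², exhaustive pair re-checks for pruning);
and statistical recovery of simulation ground truth under fixed seeds
(θ → F, MDS → planted configurations, NJ → additive trees, both Ne
estimators → true Ne = 100 within ±30% as a median over 20 replicates,
typically within ±10%). `scripts/acceptance.py` re-runs these under any
seed and emits the numbers as JSON.
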