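"""Between-individual and between-population structure.

* identity-by-state (IBS) distances between individuals,
* classical (Torgerson) metric MDS of a distance matrix,
* pairwise Weir-Cockerham F_ST (theta) between populations, combined
  across loci as a ratio of summed variance components,
* Reynolds' genetic distance -ln(1 - theta),
* neighbor-joining trees (Saitou-Nei, via scikit-bio) with Newick export.
"""
from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

from .dataset import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def to_tsv(self) -> str:
        frame = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return frame.to_csv(sep="\t")

    def to_phylip(self) -> str:
        out = io.StringIO()
        out.write(f"{len(self.labels)}\n")
        for lab, row in zip(self.labels, self.values):
            out.write(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")
        return out.getvalue()


# ----------------------------------------------------------------------
# IBS
# ----------------------------------------------------------------------

def ibs_distance(ds: GenotypeDataset, allow_missing_pairs: bool = False) -> DistanceMatrix:
    """1 - mean allele-sharing over mutually called markers, per pair.

    Shared allele count between dosages g, h is ``2 - |g - h|``; the
    similarity is its mean divided by 2.  Pairs with no mutually called
    marker raise unless ``allow_missing_pairs`` (then NaN).
    """
    calls = ds.calls.astype(np.float64)
    M = (ds.calls != MISSING).astype(np.float64)
    X = np.where(M > 0, calls, 0.0)
    n = M @ M.T
    # sum over joint markers of |g_i - g_j| via expansion of the three
    # dosage indicator matrices (avoids an O(n^2 L) python loop)
    diff = np.zeros_like(n)
    ind = [(ds.calls == k).astype(np.float64) for k in (0, 1, 2)]
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            diff += abs(a - b) * (ind[a] @ ind[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / (2.0 * n)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any() and not allow_missing_pairs:
        raise ValueError("some pairs share no called marker; set allow_missing_pairs=True")
    return DistanceMatrix(ds.sample_ids().tolist(), d)


# ----------------------------------------------------------------------
# classical MDS
# ----------------------------------------------------------------------

@dataclass
class MDSResult:
    labels: list[str]
    coordinates: np.ndarray        # (n, k)
    explained: np.ndarray          # (k,) share of the positive spectrum
    eigenvalues: np.ndarray        # full spectrum, descending


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Torgerson metric MDS: double-center -D^2/2, eigendecompose, scale
    the top-k eigenvectors by sqrt(eigenvalue).

    The explained proportion of each dimension is its eigenvalue divided
    by the sum of positive eigenvalues only.  If fewer than k positive
    eigenvalues exist, k is reduced with a warning.
    """
    n = len(D.labels)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-12).sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    pos_sum = vals[vals > 0].sum()
    explained = vals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return MDSResult(list(D.labels), coords, explained, vals)


# ----------------------------------------------------------------------
# Weir-Cockerham theta and Reynolds distance
# ----------------------------------------------------------------------

def _wc_components(ds: GenotypeDataset, idx_a: np.ndarray, idx_b: np.ndarray):
    """Per-locus Weir-Cockerham variance components (a, b, c) for two
    populations; loci monomorphic across both or uncallable in either
    population are masked out."""
    comps = []
    r = 2.0
    groups = [idx_a, idx_b]
    n_i = np.empty((2, ds.n_markers))
    p_i = np.empty((2, ds.n_markers))
    h_i = np.empty((2, ds.n_markers))
    for g, idx in enumerate(groups):
        calls = ds.calls[idx]
        called = calls != MISSING
        n_i[g] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[g] = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_i[g])
            h_i[g] = (calls == 1).sum(axis=0) / n_i[g]
    usable = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    poly = usable & (pbar > 0) & (pbar < 1) & (nbar > 1) & (nc > 0)
    return a[poly], b[poly], c[poly]


def wc_theta(ds: GenotypeDataset, idx_a, idx_b) -> float:
    """Multi-locus Weir-Cockerham theta between two sample index sets,
    as the ratio of summed variance components."""
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each population needs at least 2 individuals")
    a, b, c = _wc_components(ds, idx_a, idx_b)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


@dataclass
class PopPairStat:
    pop_a: str
    pop_b: str
    theta: float
    reynolds_d: float


def reynolds_distance(theta: float) -> float:
    """Reynolds' coancestry distance -ln(1 - theta); negative theta is
    clamped to 0, theta >= 1 gives +inf."""
    if theta >= 1.0:
        return float("inf")
    return float(-np.log(1.0 - max(theta, 0.0)))


def pairwise_fst(ds: GenotypeDataset, groups: pd.Series | None = None) -> list[PopPairStat]:
    """Weir-Cockerham theta and Reynolds distance for every pair of
    groups (default grouping: the dataset's ``group`` column)."""
    if groups is None:
        groups = ds.samples["group"]
    groups = pd.Series(groups).astype(str).reset_index(drop=True)
    labels = sorted(groups.unique())
    out = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            theta = wc_theta(
                ds, np.flatnonzero(groups == ga), np.flatnonzero(groups == gb)
            )
            out.append(PopPairStat(ga, gb, theta, reynolds_distance(theta)))
    return out


def fst_matrix(stats: list[PopPairStat], which: str = "reynolds_d") -> DistanceMatrix:
    """Assemble pairwise stats into a symmetric DistanceMatrix on the
    union of population labels (``which`` = 'theta' or 'reynolds_d';
    negative theta is clamped at 0 for matrix use)."""
    labels = sorted({s.pop_a for s in stats} | {s.pop_b for s in stats})
    pos = {l: i for i, l in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for s in stats:
        v = getattr(s, which)
        if which == "theta":
            v = max(v, 0.0)
        m[pos[s.pop_a], pos[s.pop_b]] = m[pos[s.pop_b], pos[s.pop_a]] = v
    return DistanceMatrix(labels, m)


def fst_long_table(stats: list[PopPairStat]) -> pd.DataFrame:
    """Heatmap-ready long-format table of pairwise theta / Reynolds."""
    return pd.DataFrame(
        [{"pop_a": s.pop_a, "pop_b": s.pop_b, "theta": s.theta,
          "reynolds_d": s.reynolds_d} for s in stats]
    )


# ----------------------------------------------------------------------
# neighbor-joining
# ----------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining tree of a distance matrix.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero and logged.  With fewer than 3 labels a trivial star tree is
    returned with a warning.
    """
    if len(D.labels) < 3:
        warnings.warn("fewer than 3 taxa: returning trivial tree")
        root = TreeNode(name=None)
        for lab, d in zip(D.labels, D.values[0] if len(D.labels) else []):
            root.append(TreeNode(name=lab, length=float(d) / 2.0 if len(D.labels) == 2 else 0.0))
        return root
    tree = _skbio_nj(_SkbioDM(D.values, D.labels))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("neighbor_joining: clamped %d negative branch lengths", clamped)
    return tree


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
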