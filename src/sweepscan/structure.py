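"""Population structure: allele-sharing distances, NJ tree, GRM, PCA.

The pairwise distance is the allele-sharing p-distance on unphased
dosages: one minus the mean fraction of alleles identical by state,
over pairwise-complete sites.  The neighbor-joining tree is built from
that matrix (scikit-bio's NJ, negative branch lengths clamped to zero
and logged).  PCA runs on the standard single-component genetic
relationship matrix (genotypes centred by 2p and scaled by
sqrt(2p(1-p)), missing dosages mean-imputed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# distance
# ----------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distance matrix with per-pair site counts."""

    ids: list[str]
    matrix: np.ndarray     # (n, n) float in [0, 1], zero diagonal
    n_sites: np.ndarray    # (n, n) pairwise-complete site counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def pairwise_distance(panel: GenotypePanel) -> DistanceMatrix:
    """Allele-sharing p-distance between all sample pairs.

    d(i, j) = 1 - sum_sites(2 - |g_i - g_j|) / (2 m_ij) over the m_ij
    sites where both genotypes are called.  Identical genotypes share 2
    alleles, opposite homozygotes share 0, a het shares 1 with anything.

    Raises when some pair has no pairwise-complete site.
    """
    if panel.n_samples < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    dos = panel.dosage.astype(np.int16)
    called = dos != MISSING
    n = panel.n_samples
    d = np.zeros((n, n))
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        ok = called[i] & called
        shared = np.where(ok, 2 - np.abs(dos[i] - dos), 0).sum(axis=1)
        mij = ok.sum(axis=1)
        if (mij == 0).any():
            j = int(np.flatnonzero(mij == 0)[0])
            if j != i:
                raise ValueError(
                    f"no pairwise-complete site for pair "
                    f"({panel.samples[i]}, {panel.samples[j]})")
        d[i] = 1.0 - shared / (2.0 * np.maximum(mij, 1))
        m[i] = mij
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(panel.samples), d, m)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------
def nj_tree(dist: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    Negative branch lengths (a known NJ artifact) are clamped to zero,
    with the clamp count logged.  The input must be symmetric with
    non-negative entries and at least 3 samples.
    """
    import skbio
    from skbio.tree import nj as skbio_nj

    m = np.asarray(dist.matrix, dtype=float)
    if len(dist.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if (m < 0).any():
        raise ValueError("distance matrix has negative entries")
    tree = skbio_nj(skbio.DistanceMatrix(m, dist.ids), neg_as_zero=False)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", n_clamped)
    return str(tree).strip()


def tree_bipartition(newick: str, samples: list[str]) -> np.ndarray | None:
    """Sample labels (0/1) from the deepest non-trivial split of the tree.

    Used by recovery checks: returns, for each sample, which side of
    the tree's largest internal bipartition it falls on (None when the
    tree has no non-trivial split).
    """
    from io import StringIO

    import skbio

    tree = skbio.TreeNode.read(StringIO(newick))
    n = len(samples)
    best = None
    for node in tree.non_tips():
        tips = {t.name for t in node.tips()}
        size = min(len(tips), n - len(tips))
        if 2 <= len(tips) <= n - 2 and (best is None or size > best[0]):
            best = (size, tips)
    if best is None:
        return None
    return np.array([1 if s in best[1] else 0 for s in samples])


# ----------------------------------------------------------------------
# GRM and PCA
# ----------------------------------------------------------------------
@dataclass
class GRM:
    """Single-component genetic relationship matrix."""

    ids: list[str]
    matrix: np.ndarray
    n_sites: int


def grm(panel: GenotypePanel) -> GRM:
    """Genetic relationship matrix from standardized dosages.

    G(i, j) = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))
    over the m polymorphic sites (0 < p < 1 among called alleles);
    missing dosages are mean-imputed to 2 p_k.  For unrelated samples in
    Hardy-Weinberg proportions the expected diagonal is 1.
    """
    alt, tot = panel.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for GRM")
    p = p[poly]
    dos = panel.dosage[:, poly].astype(float)
    dos = np.where(dos == MISSING, 2.0 * p, dos)
    z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = int(poly.sum())
    g = (z @ z.T) / m
    return GRM(list(panel.samples), g, m)


def pca(relationship: GRM, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the GRM, deterministic up to sign convention.

    Returns (eigenvalues desc, eigenvectors as columns); each
    eigenvector's sign is fixed so its largest-magnitude loading is
    positive.
    """
    from scipy.linalg import eigh

    g = np.asarray(relationship.matrix, dtype=float)
    n = g.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValueError("GRM is not symmetric")
    vals, vecs = eigh(g)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def pca_frame(relationship: GRM, k: int = 3) -> pd.DataFrame:
    vals, vecs = pca(relationship, k)
    df = pd.DataFrame(vecs, index=relationship.ids,
                      columns=[f"PC{i + 1}" for i in range(vecs.shape[1])])
    df.attrs["eigenvalues"] = vals
    return df
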