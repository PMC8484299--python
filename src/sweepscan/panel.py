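"""Core in-memory container for a diploid biallelic SNP panel.

The :class:`GenotypePanel` is the substrate of every statistic in the
package: a samples x sites matrix of alternate-allele dosages (0/1/2,
``-1`` for an uncalled genotype) together with per-site metadata (chrom,
1-based position, ref/alt alleles, RMS mapping quality) and an optional
per-genotype read-depth matrix.  Each sample carries exactly one of two
group labels (e.g. ``CO`` and ``VO``), which downstream statistics use to
contrast the two populations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Sentinel dosage for an uncalled genotype.
MISSING = -1


@dataclass
class GenotypePanel:
    """Diploid biallelic SNP genotypes for a two-group sample panel.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    groups : dict
        Mapping of every sample ID to its group label; exactly the
        samples of the panel, with at most two distinct labels.
    chrom, pos, ref, alt, mq : ndarray
        Per-site metadata, one entry per column of ``dosage``.  ``pos``
        is 1-based (VCF convention); ``mq`` is the RMS mapping quality.
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele dosage in {0, 1, 2}, ``-1`` when uncalled.
    depth : ndarray of int32 or None
        Per-genotype read depth (FORMAT/DP); ``None`` when absent.
    """

    samples: list[str]
    groups: dict[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    mq: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.mq = np.asarray(self.mq, dtype=float)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
        self.validate()

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} samples but dosage has {n} rows")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt"), (self.mq, "mq")):
            if len(arr) != m:
                raise ValueError(f"{name} has {len(arr)} entries for {m} sites")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        labels = set(self.groups[s] for s in self.samples)
        if len(labels) > 2:
            raise ValueError(f"more than two group labels: {sorted(labels)}")
        if m > 1:
            order = np.lexsort((self.pos, _chrom_rank(self.chrom)))
            if not np.array_equal(order, np.arange(m)):
                raise ValueError("sites must be sorted by (chrom, pos)")
            same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
            if same.any():
                i = int(np.flatnonzero(same)[0])
                raise ValueError(f"duplicate site {self.chrom[i]}:{self.pos[i + 1]}")
        if np.any(self.pos < 1):
            raise ValueError("positions must be >= 1 (1-based)")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")

    # ------------------------------------------------------------------
    # shape / group accessors
    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    @property
    def group_labels(self) -> list[str]:
        """The distinct group labels, sorted for determinism."""
        return sorted(set(self.groups[s] for s in self.samples))

    def group_mask(self, label: str) -> np.ndarray:
        """Boolean row mask selecting the samples of ``label``."""
        if label not in self.group_labels:
            raise KeyError(f"unknown group {label!r}; panel has {self.group_labels}")
        return np.array([self.groups[s] == label for s in self.samples])

    def group_dosage(self, label: str) -> np.ndarray:
        return self.dosage[self.group_mask(label)]

    # ------------------------------------------------------------------
    # per-site summaries
    # ------------------------------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def allele_counts(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, called allele count) per site.

        ``mask`` optionally restricts to a subset of samples (rows).
        """
        dos = self.dosage if mask is None else self.dosage[mask]
        called = dos != MISSING
        alt = np.where(called, dos, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def minor_allele_freq(self) -> np.ndarray:
        """MAF over called alleles; NaN where no allele is called."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the site columns in ``index`` (kept order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            mq=self.mq[index],
            dosage=self.dosage[:, index],
            depth=None if self.depth is None else self.depth[:, index],
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypePanel":
        samples = [s for s, keep in zip(self.samples, mask) if keep]
        return replace(
            self,
            samples=samples,
            groups={s: self.groups[s] for s in samples},
            dosage=self.dosage[mask],
            depth=None if self.depth is None else self.depth[mask],
        )


def _chrom_rank(chrom: np.ndarray) -> np.ndarray:
    """Rank chromosomes by first appearance so lexsort respects file order."""
    seen: dict = {}
    ranks = np.empty(len(chrom), dtype=np.int64)
    for i, c in enumerate(chrom):
        ranks[i] = seen.setdefault(c, len(seen))
    return ranks
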