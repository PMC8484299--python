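"""Windowed population-genetic statistics.

Implements per-site nucleotide diversity (mean pairwise difference),
Weir & Cockerham (1984) two-population Fst variance components with
ratio-of-sums window weighting, Tajima's D, and genotype-based linkage
disequilibrium (r^2) with a binned decay curve.

Windows are 0-based half-open internally; the default scan uses 20-kb
windows with a 10-kb step.  Per-window diversity is reported per bp of
window span, following the usual sliding-window convention, so values
are comparable across truncated terminal windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# windows
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``size`` bp windows every ``step`` bp."""

    size: int = 20_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")
        if self.step > self.size:
            raise ValueError(f"step {self.step} exceeds window size {self.size}")


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Tile each chromosome with sliding windows.

    Windows start at 0 and advance by ``spec.step``; the last windows
    are truncated at the chromosome end, and no window starts at or
    beyond the chromosome length.  Returns a DataFrame with columns
    ``chrom, start, end`` (0-based half-open).
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + spec.size, length)))
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_site_indices(panel: GenotypePanel, windows: pd.DataFrame) -> list[np.ndarray]:
    """Per-window arrays of panel site indices falling inside the window.

    A site at 1-based position ``pos`` lies in 0-based half-open window
    [start, end) iff start < pos <= end.
    """
    out = []
    by_chrom: dict = {}
    for chrom in dict.fromkeys(windows["chrom"]):
        mask = panel.chrom == chrom
        by_chrom[chrom] = (np.flatnonzero(mask), panel.pos[mask])
    for chrom, start, end in windows.itertuples(index=False):
        idx, pos = by_chrom.get(chrom, (np.empty(0, dtype=np.int64),) * 2)
        lo = np.searchsorted(pos, start + 1, side="left")
        hi = np.searchsorted(pos, end, side="right")
        out.append(idx[lo:hi])
    return out


# ----------------------------------------------------------------------
# nucleotide diversity
# ----------------------------------------------------------------------
def site_pi(alt_count, allele_count):
    """Unbiased per-site mean pairwise difference 2j(n-j)/(n(n-1)).

    ``alt_count`` (j) and ``allele_count`` (n) may be scalars or arrays;
    entries with n < 2 yield NaN (undefined, skipped by callers).
    """
    j = np.asarray(alt_count, dtype=float)
    n = np.asarray(allele_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (n * np.maximum(n - 1.0, 1.0)), np.nan)
    if pi.ndim == 0:
        return float(pi)
    return pi


def windowed_pi(panel: GenotypePanel, group: str, windows: pd.DataFrame) -> np.ndarray:
    """Per-window nucleotide diversity (theta-pi) per bp for one group.

    Sums per-site pairwise diversity over the window and divides by the
    window span in bp (truncated windows use their actual span).  A
    window with no polymorphic site gets 0.
    """
    alt, tot = panel.allele_counts(panel.group_mask(group))
    persite = site_pi(alt, tot)
    persite = np.where(np.isnan(persite), 0.0, persite)
    spans = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    sums = np.array([persite[idx].sum() for idx in window_site_indices(panel, windows)])
    return sums / spans


# ----------------------------------------------------------------------
# Weir & Cockerham Fst
# ----------------------------------------------------------------------
def group_site_stats(panel: GenotypePanel, group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called_diploids, alt freq, het freq) for one group."""
    dos = panel.group_dosage(group)
    called = dos != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dos, 0).sum(axis=0) / np.maximum(2.0 * n, 1.0)
        h = (dos == 1).sum(axis=0) / np.maximum(n, 1.0)
    p = np.where(n > 0, p, np.nan)
    h = np.where(n > 0, h, np.nan)
    return n, p, h


def wc_fst_site(n1, p1, h1, n2, p2, h2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components for two populations.

    Parameters are per-population called diploid counts ``n_i``,
    alternate-allele frequencies ``p_i`` and observed heterozygote
    frequencies ``h_i`` (scalars or arrays).  Returns the components
    ``(a, b, c)``: among-population, among-individual-within-population
    and within-individual.  The site estimate is a/(a+b+c); windows sum
    components before dividing (ratio of sums).

    Sites where either population has fewer than 2 called diploids give
    NaN components.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n1 ** 2 + n2 ** 2) / nsum) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum

        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    ok = (n1 >= 2) & (n2 >= 2)
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    if a.ndim == 0:
        return float(a), float(b), float(c)
    return a, b, c


def fst_components(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-site WC84 (a, a+b+c) for the panel's two groups.

    Sites that are unusable (either group under 2 called diploids) or
    monomorphic across both groups (zero denominator) return NaN in
    both entries and contribute nothing to window sums.
    """
    ga, gb = panel.group_labels
    if len(panel.group_labels) != 2:
        raise ValueError("Fst requires exactly two groups")
    n1, p1, h1 = group_site_stats(panel, ga)
    n2, p2, h2 = group_site_stats(panel, gb)
    a, b, c = wc_fst_site(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    bad = np.isnan(denom) | (denom == 0)
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)
    return a, denom


def windowed_fst(panel: GenotypePanel, windows: pd.DataFrame) -> np.ndarray:
    """Ratio-of-sums WC84 Fst per window; NaN where no usable site.

    Negative estimates are retained (not clamped): they are the
    estimator's way of saying "no differentiation".
    """
    a, denom = fst_components(panel)
    a0 = np.where(np.isnan(a), 0.0, a)
    d0 = np.where(np.isnan(denom), 0.0, denom)
    out = np.empty(len(windows))
    for w, idx in enumerate(window_site_indices(panel, windows)):
        dsum = d0[idx].sum()
        out[w] = a0[idx].sum() / dsum if dsum > 0 else np.nan
    return out


def mean_site_fst(panel: GenotypePanel) -> float:
    """Genome-wide ratio-of-sums WC84 Fst over all usable sites."""
    a, denom = fst_components(panel)
    d = np.nansum(denom)
    return float(np.nansum(a) / d) if d > 0 else float("nan")


# ----------------------------------------------------------------------
# Tajima's D
# ----------------------------------------------------------------------
@dataclass
class TajimaResult:
    """Tajima's D for one population over one scope (window or genome)."""

    population: str
    n: int
    S: int
    pi_sum: float
    D: float  # NaN when undefined (S == 0 or n < 4)


def tajima_constants(n: int) -> dict[str, float]:
    # Tajima (1989) a1..e2 as functions of the allele count n
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_sum: float, n: int, population: str = "") -> TajimaResult:
    """Tajima's D from segregating sites S, summed pairwise diversity and n.

    ``pi_sum`` is the sum over sites of the per-site mean pairwise
    difference; ``n`` is the number of sequences (alleles).  Undefined
    (NaN) when S == 0 or n < 4.
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    if n < 4 or S == 0:
        if n < 4:
            logger.info("tajimas_d: n=%d < 4, undefined", n)
        return TajimaResult(population, n, S, pi_sum, float("nan"))
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    d = (pi_sum - theta_w) / np.sqrt(var)
    return TajimaResult(population, n, S, pi_sum, float(d))


def windowed_tajimas_d(panel: GenotypePanel, group: str, windows: pd.DataFrame) -> pd.DataFrame:
    """Tajima's D per window for one group.

    Uses the nominal allele count n = 2 x (group sample count); S and
    pi are computed from called alleles, so light missingness (capped
    at 10% by the site filters) introduces only a bounded approximation.
    """
    mask = panel.group_mask(group)
    n = 2 * int(mask.sum())
    alt, tot = panel.allele_counts(mask)
    seg = (alt > 0) & (alt < tot)
    persite = site_pi(alt, tot)
    persite = np.where(np.isnan(persite), 0.0, persite)
    rows = []
    for (chrom, start, end), idx in zip(
            windows.itertuples(index=False), window_site_indices(panel, windows)):
        res = tajimas_d(int(seg[idx].sum()), float(persite[idx].sum()), n, group)
        rows.append((chrom, start, end, res.S, res.pi_sum, res.D))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "S", "pi_sum", "tajima_d"])


def genome_tajimas_d(panel: GenotypePanel, group: str) -> TajimaResult:
    mask = panel.group_mask(group)
    n = 2 * int(mask.sum())
    alt, tot = panel.allele_counts(mask)
    seg = (alt > 0) & (alt < tot)
    persite = site_pi(alt, tot)
    return tajimas_d(int(seg.sum()), float(np.nansum(persite)), n, group)


# ----------------------------------------------------------------------
# linkage disequilibrium
# ----------------------------------------------------------------------
def ld_r2(dosage_x: np.ndarray, dosage_y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages at two sites.

    Computed over pairwise-complete samples (both genotypes called).
    NaN when fewer than 2 complete pairs or either site has zero
    variance among them.
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov ** 2 / (vx * vy))


@dataclass
class LDDecayCurve:
    """Binned mean r^2 versus physical distance for one group."""

    bin_mid: np.ndarray      # bp, ordered
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_distance: float  # bp; NaN when the curve never halves

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_midpoint": self.bin_mid,
                             "mean_r2": self.mean_r2,
                             "n_pairs": self.n_pairs})


def ld_decay(
    panel: GenotypePanel,
    group: str,
    max_dist: int = 5_000_000,
    bin_width: int = 50_000,
    min_maf: float = 0.05,
    block: int = 512,
) -> LDDecayCurve:
    """LD decay curve: mean pairwise r^2 binned by distance.

    All intra-chromosome site pairs with separation <= ``max_dist`` and
    both MAFs >= ``min_maf`` contribute.  r^2 uses pairwise-complete
    samples (computed blockwise for speed).  The half-decay distance is
    the smallest bin midpoint whose mean r^2 drops to half of the
    maximum bin mean.
    """
    sub = panel.take_samples(panel.group_mask(group))
    maf = sub.minor_allele_freq()
    keep = ~np.isnan(maf) & (maf >= min_maf)
    sub = sub.take_sites(keep)

    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for chrom in dict.fromkeys(sub.chrom):
        cmask = sub.chrom == chrom
        pos = sub.pos[cmask]
        dos = sub.dosage[:, cmask].astype(float)
        m = dos.shape[1]
        if m < 2:
            continue
        valid = dos != MISSING
        x = np.where(valid, dos, 0.0)
        v = valid.astype(float)
        for j0 in range(0, m, block):
            j1 = min(j0 + block, m)
            # pairwise-complete sums between block columns and all later columns
            nxy = v[:, j0:j1].T @ v           # complete-pair counts
            sx = x[:, j0:j1].T @ v
            sy = v[:, j0:j1].T @ x
            sxx = (x[:, j0:j1] ** 2).T @ v
            syy = v[:, j0:j1].T @ (x ** 2)
            sxy = x[:, j0:j1].T @ x
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / nxy
                varx = sxx - sx ** 2 / nxy
                vary = syy - sy ** 2 / nxy
                r2 = cov ** 2 / (varx * vary)
            dist = np.abs(pos[None, :] - pos[j0:j1, None])
            jj, kk = np.meshgrid(np.arange(j0, j1), np.arange(m), indexing="ij")
            use = (kk > jj) & (dist <= max_dist) & (nxy >= 2) & np.isfinite(r2)
            if not use.any():
                continue
            bins = np.minimum(dist[use] // bin_width, n_bins - 1).astype(np.int64)
            np.add.at(sums, bins, r2[use])
            np.add.at(counts, bins, 1)

    has = counts > 0
    if not has.any():
        logger.warning("ld_decay(%s): no eligible site pairs", group)
        return LDDecayCurve(np.empty(0), np.empty(0), np.empty(0, dtype=np.int64),
                            float("nan"))
    mids = (np.arange(n_bins) + 0.5) * bin_width
    mean_r2 = np.where(has, sums / np.maximum(counts, 1), np.nan)
    mids, mean_r2, counts = mids[has], mean_r2[has], counts[has]
    half = 0.5 * np.nanmax(mean_r2)
    below = np.flatnonzero(mean_r2 <= half)
    half_dist = float(mids[below[0]]) if below.size else float("nan")
    return LDDecayCurve(mids, mean_r2, counts, half_dist)
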