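"""Selective-sweep scan and SNP screening utilities.

The scan contrasts two groups (a reference group A, e.g. the common
type, and a focal group B) over sliding windows: window Fst values are
Z-transformed, per-window diversity ratios log2(theta_pi_A /
theta_pi_B) are formed, and windows falling simultaneously in the top
5% of Z(Fst) and in a 5% tail of the ratio are called candidate sweep
outliers — the upper ratio tail marks diversity loss in B (B-selected),
the lower tail in A (A-selected).  Outlier windows merge into regions,
which are intersected with gene models.

Also here: precedence-based SNP region annotation against gene models
and group-diagnostic marker screening (sites fixed for alternative
alleles in the two groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel
from .popgen import windowed_fst, windowed_pi
from .variant_io import GeneModel

logger = logging.getLogger(__name__)

DIRECTION_NONE = "none"


# ----------------------------------------------------------------------
# scan table
# ----------------------------------------------------------------------
def zscore_fst(fst: np.ndarray) -> np.ndarray:
    """Z-transform window Fst: (Fst - mean) / SD over defined windows.

    NaN entries (undefined Fst) are excluded from the mean/SD and stay
    NaN in the output.  A degenerate scan (SD == 0 or fewer than two
    defined values) raises.
    """
    fst = np.asarray(fst, dtype=float)
    ok = np.isfinite(fst)
    if ok.sum() < 2:
        raise ValueError("zscore_fst needs at least 2 defined Fst values")
    mu = fst[ok].mean()
    sd = fst[ok].std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("zscore_fst: zero standard deviation (degenerate scan)")
    out = np.full_like(fst, np.nan)
    out[ok] = (fst[ok] - mu) / sd
    return out


def log2_pi_ratio(pi_a: np.ndarray, pi_b: np.ndarray) -> np.ndarray:
    """log2(theta_pi_A / theta_pi_B) per window; NaN where either is <= 0.

    Windows with zero diversity in either group are flagged ineligible
    by the NaN rather than producing +/-inf.
    """
    pi_a = np.asarray(pi_a, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    ok = (pi_a > 0) & (pi_b > 0)
    out = np.full(np.broadcast(pi_a, pi_b).shape, np.nan)
    out[ok] = np.log2(pi_a[ok] / pi_b[ok])
    return out


def build_scan_table(
    panel: GenotypePanel,
    windows: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Assemble the per-window scan table (before outlier calling).

    Columns: chrom, start, end, n_snps, pi_a, pi_b, fst, log2_ratio.
    ``group_a`` is the reference group of the ratio's numerator.
    """
    from .popgen import window_site_indices

    table = windows[["chrom", "start", "end"]].copy()
    table["n_snps"] = [len(i) for i in window_site_indices(panel, windows)]
    table["pi_a"] = windowed_pi(panel, group_a, windows)
    table["pi_b"] = windowed_pi(panel, group_b, windows)
    table["fst"] = windowed_fst(panel, windows)
    table["log2_ratio"] = log2_pi_ratio(table["pi_a"].to_numpy(), table["pi_b"].to_numpy())
    return table


def joint_outliers(
    scan: pd.DataFrame,
    q: float = 0.05,
    min_snps: int = 10,
    group_a: str = "A",
    group_b: str = "B",
) -> pd.DataFrame:
    """Call joint Fst x diversity-ratio outlier windows.

    A window is *eligible* when its Fst is defined, both group
    diversities are positive and it holds at least ``min_snps`` SNPs.
    Z(Fst) and the empirical quantiles (type-7 order statistics, ties
    at the threshold included) are computed over eligible windows only.

    Direction calls:

    * B-selected: Z(Fst) >= (1-q) quantile AND log2 ratio >= (1-q)
      quantile (diversity depressed in B);
    * A-selected: Z(Fst) >= (1-q) quantile AND log2 ratio <= q quantile.

    Returns the scan table with ``eligible``, ``z_fst`` and
    ``direction`` columns added; raises when fewer than 20 windows are
    eligible (empirical quantiles would be meaningless).
    """
    out = scan.copy()
    eligible = (
        np.isfinite(out["fst"].to_numpy())
        & (out["pi_a"].to_numpy() > 0)
        & (out["pi_b"].to_numpy() > 0)
        & (out["n_snps"].to_numpy() >= min_snps)
    )
    n_elig = int(eligible.sum())
    if n_elig < 20:
        raise ValueError(f"only {n_elig} eligible windows; need >= 20 for quantiles")
    out["eligible"] = eligible

    z = np.full(len(out), np.nan)
    fst_elig = out.loc[eligible, "fst"].to_numpy()
    z_elig = zscore_fst(fst_elig)
    z[eligible] = z_elig
    out["z_fst"] = z

    ratio_elig = out.loc[eligible, "log2_ratio"].to_numpy()
    z_hi = np.quantile(z_elig, 1.0 - q)
    r_hi = np.quantile(ratio_elig, 1.0 - q)
    r_lo = np.quantile(ratio_elig, q)

    direction = np.full(len(out), DIRECTION_NONE, dtype=object)
    sel_b = eligible & (z >= z_hi) & (out["log2_ratio"].to_numpy() >= r_hi)
    sel_a = eligible & (z >= z_hi) & (out["log2_ratio"].to_numpy() <= r_lo)
    direction[sel_b] = f"{group_b}-selected"
    direction[sel_a] = f"{group_a}-selected"
    out["direction"] = direction
    logger.info("joint_outliers: %d eligible windows, %d %s-selected, %d %s-selected",
                n_elig, int(sel_b.sum()), group_b, int(sel_a.sum()), group_a)
    return out


# ----------------------------------------------------------------------
# regions
# ----------------------------------------------------------------------
@dataclass
class SweepRegion:
    """A merged run of same-direction outlier windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    direction: str
    n_windows: int
    min_z: float
    max_z: float
    genes: list[str] | None = None


def merge_regions(scan: pd.DataFrame) -> list[SweepRegion]:
    """Merge overlapping or abutting same-direction outlier windows.

    Windows of opposite directions never merge.  The result is
    independent of the input row order and idempotent.
    """
    out: list[SweepRegion] = []
    calls = scan[scan["direction"] != DIRECTION_NONE]
    for (chrom, direction), grp in calls.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start <= cur.end:
                cur.end = max(cur.end, row.end)
                cur.n_windows += 1
                cur.min_z = min(cur.min_z, row.z_fst)
                cur.max_z = max(cur.max_z, row.z_fst)
            else:
                if cur is not None:
                    out.append(cur)
                cur = SweepRegion(chrom, int(row.start), int(row.end), direction,
                                  1, float(row.z_fst), float(row.z_fst))
        if cur is not None:
            out.append(cur)
    out.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return out


def genes_in_regions(regions: list[SweepRegion], genes: list[GeneModel]) -> list[SweepRegion]:
    """Attach the IDs of genes whose span overlaps each region by >= 1 bp.

    Gene spans are 1-based inclusive; regions 0-based half-open, so a
    gene overlaps iff gene.start <= region.end and gene.end > region.start
    (comparing the gene's 1-based coordinates with the region's 0-based
    bounds after conversion).
    """
    for region in regions:
        hits = [
            g.gene_id for g in genes
            if g.chrom == region.chrom
            and g.start - 1 < region.end
            and g.end > region.start
        ]
        region.genes = hits
    return regions


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.direction, r.n_windows, r.min_z, r.max_z,
          ",".join(r.genes) if r.genes else "")
         for r in regions],
        columns=["chrom", "start", "end", "direction", "n_windows",
                 "min_z", "max_z", "genes"],
    )


def regions_to_bed(regions: list[SweepRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\n")


# ----------------------------------------------------------------------
# SNP region annotation
# ----------------------------------------------------------------------
#: Annotation categories from highest to lowest precedence.
CATEGORIES = ("exonic", "splicing", "UTR5", "UTR3", "intronic",
              "upstream", "downstream", "intergenic")
_PRio = {c: i for i, c in enumerate(CATEGORIES)}


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _categorize_in_gene(pos: int, g: GeneModel, upstream: int, splice: int) -> str | None:
    """Category of a 1-based position relative to one gene, or None."""
    if g.start <= pos <= g.end:
        if _in_any(pos, g.cds):
            return "exonic"
        exons = g.exons if g.exons else (g.cds if g.cds else [(g.start, g.end)])
        # splicing: within `splice` bp of an exon boundary, intronic side
        for s, e in exons:
            if (s - splice <= pos < s or e < pos <= e + splice) and g.start <= pos <= g.end:
                if not _in_any(pos, exons):
                    return "splicing"
        if _in_any(pos, g.utr5):
            return "UTR5"
        if _in_any(pos, g.utr3):
            return "UTR3"
        if _in_any(pos, exons):
            return "exonic"
        return "intronic"
    # flanks, strand-aware
    if g.strand == "-":
        up = (g.end + 1, g.end + upstream)
        down = (g.start - upstream, g.start - 1)
    else:
        up = (g.start - upstream, g.start - 1)
        down = (g.end + 1, g.end + upstream)
    if up[0] <= pos <= up[1]:
        return "upstream"
    if down[0] <= pos <= down[1]:
        return "downstream"
    return None


def annotate_snps(
    panel: GenotypePanel,
    genes: list[GeneModel],
    upstream: int = 1000,
    splice: int = 2,
) -> pd.DataFrame:
    """Assign each SNP one region category by precedence.

    Precedence: exonic > splicing > UTR5 > UTR3 > intronic > upstream >
    downstream > intergenic.  A SNP in the context of several genes gets
    the highest-precedence category over all of them.  Returns a
    DataFrame (chrom, pos, category); see :func:`annotation_tally` for
    the summary table.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    cats = []
    for chrom, pos in zip(panel.chrom, panel.pos):
        best = "intergenic"
        for g in by_chrom.get(chrom, ()):
            if pos < g.start - upstream or pos > g.end + upstream:
                continue
            cat = _categorize_in_gene(int(pos), g, upstream, splice)
            if cat is not None and _PRio[cat] < _PRio[best]:
                best = cat
                if best == "exonic":
                    break
        cats.append(best)
    return pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos, "category": cats})


def annotation_tally(annotated: pd.DataFrame) -> pd.DataFrame:
    """Category counts and percentages; rows cover all categories."""
    counts = annotated["category"].value_counts()
    total = len(annotated)
    rows = [(c, int(counts.get(c, 0)),
             100.0 * counts.get(c, 0) / total if total else 0.0)
            for c in CATEGORIES]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


# ----------------------------------------------------------------------
# diagnostic markers
# ----------------------------------------------------------------------
@dataclass
class DiagnosticMarker:
    """A SNP fixed for alternative alleles in the two groups."""

    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    call_rate_a: float
    call_rate_b: float


def diagnostic_markers(
    panel: GenotypePanel,
    max_miss: float = 0.1,
    strict: bool = True,
    min_freq_diff: float = 0.8,
) -> list[DiagnosticMarker]:
    """Screen for group-diagnostic SNP markers.

    Strict mode: every called genotype in group A is homozygous for one
    allele and every called genotype in group B homozygous for the
    other, with per-group missingness <= ``max_miss``.  Relaxed mode:
    absolute allele-frequency difference >= ``min_freq_diff`` (same
    missingness cap); the reported alleles are each group's major
    allele.
    """
    ga, gb = panel.group_labels
    dos_a = panel.group_dosage(ga)
    dos_b = panel.group_dosage(gb)
    na, nb = dos_a.shape[0], dos_b.shape[0]

    called_a = dos_a != MISSING
    called_b = dos_b != MISSING
    miss_ok = ((1 - called_a.mean(axis=0)) <= max_miss) & \
              ((1 - called_b.mean(axis=0)) <= max_miss)
    any_called = called_a.any(axis=0) & called_b.any(axis=0)

    markers: list[DiagnosticMarker] = []
    if strict:
        a_all0 = np.all(np.where(called_a, dos_a == 0, True), axis=0)
        a_all2 = np.all(np.where(called_a, dos_a == 2, True), axis=0)
        b_all0 = np.all(np.where(called_b, dos_b == 0, True), axis=0)
        b_all2 = np.all(np.where(called_b, dos_b == 2, True), axis=0)
        hit = miss_ok & any_called & ((a_all0 & b_all2) | (a_all2 & b_all0))
        which_a_ref = a_all0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = np.where(called_a, dos_a, 0).sum(axis=0) / np.maximum(2 * called_a.sum(axis=0), 1)
            pb = np.where(called_b, dos_b, 0).sum(axis=0) / np.maximum(2 * called_b.sum(axis=0), 1)
        hit = miss_ok & any_called & (np.abs(pa - pb) >= min_freq_diff)
        which_a_ref = pa < 0.5

    for j in np.flatnonzero(hit):
        ref, alt = str(panel.ref[j]), str(panel.alt[j])
        allele_a, allele_b = (ref, alt) if which_a_ref[j] else (alt, ref)
        markers.append(DiagnosticMarker(
            chrom=str(panel.chrom[j]), pos=int(panel.pos[j]),
            allele_a=allele_a, allele_b=allele_b,
            call_rate_a=float(called_a[:, j].mean()),
            call_rate_b=float(called_b[:, j].mean()),
        ))
    logger.info("diagnostic_markers: %d markers (%s vs %s, strict=%s)",
                len(markers), ga, gb, strict)
    return markers


def markers_to_frame(markers: list[DiagnosticMarker], group_a: str, group_b: str) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.chrom, m.pos, m.allele_a, m.allele_b, m.call_rate_a, m.call_rate_b)
         for m in markers],
        columns=["chrom", "pos", f"allele_{group_a}", f"allele_{group_b}",
                 f"call_rate_{group_a}", f"call_rate_{group_b}"],
    )
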