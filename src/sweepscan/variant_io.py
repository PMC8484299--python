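"""VCF / GFF3 input-output and hard SNP quality filtering.

Reading goes through cyvcf2 (VCF) and gffutils (GFF3).  Only biallelic
SNP records enter the panel; indels and multiallelic records are dropped
and counted.  The quality filters mirror a standard resequencing
pipeline: per-genotype depth bounds (genotypes outside [min_dp, max_dp]
become missing), then site-level RMS mapping quality, minor-allele
frequency over called alleles, and missingness caps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

_NUCS = frozenset("ACGT")


# ----------------------------------------------------------------------
# group table
# ----------------------------------------------------------------------
def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample ID -> group label."""
    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sample, group = parts
        if sample in groups:
            raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
        groups[sample] = group
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"group table must define exactly 2 groups, got {labels}")
    return groups


def write_group_table(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_vcf(path: str | Path, group_table: dict[str, str] | str | Path) -> GenotypePanel:
    """Read biallelic SNP records from a VCF 4.x file into a panel.

    Indel and multiallelic records are skipped (and logged).  FORMAT/DP
    is kept when present; INFO/MQ is read as the site RMS mapping
    quality (NaN when absent).

    Raises
    ------
    ValueError
        If a VCF sample is absent from the group table, or no usable
        record remains.
    """
    from cyvcf2 import VCF

    if not isinstance(group_table, dict):
        group_table = read_group_table(group_table)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in group_table:
            raise ValueError(f"VCF sample {s!r} is missing from the group table")

    chrom, pos, ref, alt, mq = [], [], [], [], []
    dosage_cols, depth_cols = [], []
    n_indel = n_multi = n_other = 0
    has_depth = True
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if v.is_indel or not v.is_snp:
            n_indel += 1
            continue
        r, a = v.REF.upper(), v.ALT[0].upper()
        if r not in _NUCS or a not in _NUCS:
            n_other += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(r)
        alt.append(a)
        info_mq = v.INFO.get("MQ")
        mq.append(float(info_mq) if info_mq is not None else np.nan)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosage_cols.append(dos.astype(np.int8))
        if has_depth:
            dp = v.format("DP")
            if dp is None:
                has_depth = False
            else:
                depth_cols.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32))
    vcf.close()

    if n_indel or n_multi or n_other:
        logger.info(
            "read_vcf(%s): dropped %d indel, %d multiallelic, %d non-ACGT records",
            path, n_indel, n_multi, n_other,
        )
    if not chrom:
        raise ValueError(f"no usable biallelic SNP records in {path}")

    dosage = np.column_stack(dosage_cols)
    depth = np.column_stack(depth_cols) if has_depth and depth_cols else None
    order = np.lexsort((np.asarray(pos), _first_seen_rank(chrom)))
    panel = GenotypePanel(
        samples=samples,
        groups={s: group_table[s] for s in samples},
        chrom=np.asarray(chrom, dtype=object)[order],
        pos=np.asarray(pos, dtype=np.int64)[order],
        ref=np.asarray(ref, dtype=object)[order],
        alt=np.asarray(alt, dtype=object)[order],
        mq=np.asarray(mq, dtype=float)[order],
        dosage=dosage[:, order],
        depth=None if depth is None else depth[:, order],
    )
    logger.info("read_vcf(%s): %d samples x %d sites", path, panel.n_samples, panel.n_sites)
    return panel


def _first_seen_rank(chroms: list) -> np.ndarray:
    seen: dict = {}
    return np.array([seen.setdefault(c, len(seen)) for c in chroms], dtype=np.int64)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel back out as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if panel.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        fmt = "GT:DP" if panel.depth is not None else "GT"
        for j in range(panel.n_sites):
            info = "." if np.isnan(panel.mq[j]) else f"MQ={panel.mq[j]:g}"
            cells = []
            for i in range(panel.n_samples):
                gt = _GT_STR[int(panel.dosage[i, j])]
                if panel.depth is not None:
                    cells.append(f"{gt}:{int(panel.depth[i, j])}")
                else:
                    cells.append(gt)
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j]}\t.\t{panel.ref[j]}\t{panel.alt[j]}"
                     f"\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells) + "\n")


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------
def filter_genotypes(panel: GenotypePanel, min_dp: int = 3, max_dp: int = 50) -> GenotypePanel:
    """Set genotypes with depth outside [min_dp, max_dp] to missing.

    Depth bounds are applied per genotype (FORMAT/DP), so a failing
    genotype becomes missing without discarding the whole site.  Panels
    without depth information pass through unchanged (logged).
    """
    if panel.depth is None:
        logger.warning("filter_genotypes: panel has no depth; passing through")
        return panel
    bad = (panel.depth < min_dp) | (panel.depth > max_dp)
    n_masked = int((bad & (panel.dosage != MISSING)).sum())
    dosage = np.where(bad, np.int8(MISSING), panel.dosage)
    logger.info("filter_genotypes: masked %d genotypes outside DP [%d, %d]",
                n_masked, min_dp, max_dp)
    out = GenotypePanel(
        samples=panel.samples, groups=panel.groups, chrom=panel.chrom,
        pos=panel.pos, ref=panel.ref, alt=panel.alt, mq=panel.mq,
        dosage=dosage, depth=panel.depth,
    )
    return out


@dataclass
class FilterTally:
    """Per-rule site-removal bookkeeping for :func:`filter_sites`.

    A removed site is attributed to the *first* failing rule in the
    order mq -> maf -> miss, so the tallies are deterministic and sum
    with ``n_kept`` to ``n_input``.
    """

    n_input: int
    removed_mq: int
    removed_maf: int
    removed_miss: int
    n_kept: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tcount\n")
            for key, val in asdict(self).items():
                fh.write(f"{key}\t{val}\n")


def filter_sites(
    panel: GenotypePanel,
    min_mq: float = 20.0,
    min_maf: float = 0.05,
    max_miss: float = 0.1,
) -> tuple[GenotypePanel, FilterTally]:
    """Apply site-level hard filters; return the kept panel and a tally.

    A site is kept iff RMS mapping quality >= ``min_mq``, minor-allele
    frequency over *called* alleles >= ``min_maf``, and the fraction of
    missing genotypes <= ``max_miss``.  Sites with NaN mapping quality
    pass the mq rule (quality unknown, not low).
    """
    mq_ok = np.isnan(panel.mq) | (panel.mq >= min_mq)
    maf = panel.minor_allele_freq()
    maf_ok = ~np.isnan(maf) & (maf >= min_maf)
    miss_ok = panel.missing_fraction() <= max_miss

    keep = mq_ok & maf_ok & miss_ok
    removed_mq = int((~mq_ok).sum())
    removed_maf = int((mq_ok & ~maf_ok).sum())
    removed_miss = int((mq_ok & maf_ok & ~miss_ok).sum())
    tally = FilterTally(
        n_input=panel.n_sites,
        removed_mq=removed_mq,
        removed_maf=removed_maf,
        removed_miss=removed_miss,
        n_kept=int(keep.sum()),
    )
    logger.info("filter_sites: kept %d/%d (mq-fail %d, maf-fail %d, miss-fail %d)",
                tally.n_kept, tally.n_input, removed_mq, removed_maf, removed_miss)
    if tally.n_kept == 0:
        logger.warning("filter_sites: no sites survived the filters")
    return panel.take_sites(keep), tally


# ----------------------------------------------------------------------
# GFF3
# ----------------------------------------------------------------------
@dataclass
class GeneModel:
    """A gene with optional exon/CDS/UTR substructure (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = None
    cds: list[tuple[int, int]] = None
    utr5: list[tuple[int, int]] = None
    utr3: list[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for name in ("exons", "cds", "utr5", "utr3"):
            if getattr(self, name) is None:
                setattr(self, name, [])
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        for name in ("exons", "cds", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if not (self.start <= s <= e <= self.end):
                    raise ValueError(
                        f"gene {self.gene_id}: child interval [{s},{e}] outside span")


_UTR5_TYPES = {"five_prime_UTR", "5UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR", "three_prime_utr"}


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon/CDS/UTR children) from a GFF3 file.

    Coordinates are kept 1-based inclusive as in the file.  A feature
    line whose end precedes its start raises with the line number.
    """
    import gffutils

    # gffutils reports no line numbers, so validate coordinates first.
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end < start:
            raise ValueError(f"{path}:{lineno}: end {end} < start {start}")

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand or "+",
            start=g.start, end=g.end,
        )
        for child in db.children(g):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                model.exons.append(iv)
            elif child.featuretype == "CDS":
                model.cds.append(iv)
            elif child.featuretype in _UTR5_TYPES:
                model.utr5.append(iv)
            elif child.featuretype in _UTR3_TYPES:
                model.utr3.append(iv)
        for name in ("exons", "cds", "utr5", "utr3"):
            getattr(model, name).sort()
        genes.append(model)
    logger.info("read_gff3(%s): %d genes", path, len(genes))
    return genes
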