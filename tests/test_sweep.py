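"""Sweep scan: Z(Fst), diversity ratio, joint outliers, regions, annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_panel
from sweepscan.panel import MISSING
from sweepscan.sweep import (annotate_snps, annotation_tally,
                             diagnostic_markers, genes_in_regions,
                             joint_outliers, log2_pi_ratio, merge_regions,
                             zscore_fst)
from sweepscan.variant_io import GeneModel


# ----------------------------------------------------------------------
# Z(Fst) and the ratio
# ----------------------------------------------------------------------
def test_zscore_fst_worked_example():
    np.testing.assert_allclose(zscore_fst([0.1, 0.2, 0.3]), [-1, 0, 1],
                               atol=1e-12)


def test_zscore_fst_constant_vector_errors():
    with pytest.raises(ValueError, match="zero standard deviation"):
        zscore_fst([0.4, 0.4, 0.4])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=50,
                unique=True))
def test_zscore_fst_output_standardized(vals):
    z = zscore_fst(np.array(vals))
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_log2_pi_ratio_values():
    out = log2_pi_ratio(np.array([0.002, 0.001, 0.001]),
                        np.array([0.0005, 0.001, 0.0]))
    assert out[0] == pytest.approx(2.0)
    assert out[1] == pytest.approx(0.0)
    assert np.isnan(out[2])            # zero diversity: ineligible, not -inf


# ----------------------------------------------------------------------
# joint outlier calling
# ----------------------------------------------------------------------
def _random_scan(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 10_000,
        "end": np.arange(n) * 10_000 + 20_000,
        "n_snps": 50,
        "pi_a": rng.lognormal(-8, 0.5, n),
        "pi_b": rng.lognormal(-8, 0.5, n),
        "fst": rng.uniform(0, 1, n),
    })


def test_joint_outliers_bounded_by_quantile():
    scan = _random_scan()
    scan["log2_ratio"] = log2_pi_ratio(scan.pi_a.to_numpy(), scan.pi_b.to_numpy())
    out = joint_outliers(scan, q=0.05)
    for d in ("A-selected", "B-selected"):
        assert (out.direction == d).sum() <= math.ceil(0.05 * len(out))
    assert set(out.loc[out.direction != "none"].index) <= \
        set(out.loc[out.eligible].index)


def test_joint_outliers_requires_both_tails():
    scan = _random_scan(seed=1)
    scan.loc[10, "fst"] = 5.0                       # top Z ...
    scan.loc[10, "pi_a"] = scan.loc[10, "pi_b"]     # ... but median ratio
    scan["log2_ratio"] = log2_pi_ratio(scan.pi_a.to_numpy(), scan.pi_b.to_numpy())
    out = joint_outliers(scan, q=0.05)
    assert out.loc[10, "direction"] == "none"


def test_joint_outliers_too_few_windows_errors():
    scan = _random_scan(n=15)
    scan["log2_ratio"] = log2_pi_ratio(scan.pi_a.to_numpy(), scan.pi_b.to_numpy())
    with pytest.raises(ValueError, match="eligible windows"):
        joint_outliers(scan)


def test_joint_outliers_min_snps_gates_eligibility():
    scan = _random_scan(seed=2)
    scan.loc[:4, "n_snps"] = 3
    scan["log2_ratio"] = log2_pi_ratio(scan.pi_a.to_numpy(), scan.pi_b.to_numpy())
    out = joint_outliers(scan, min_snps=10)
    assert not out.loc[:4, "eligible"].any()
    assert (out.loc[:4, "direction"] == "none").all()


# ----------------------------------------------------------------------
# regions
# ----------------------------------------------------------------------
def _scan_rows(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "z_fst",
                                       "direction"])


def test_merge_regions_overlap_and_gap():
    scan = _scan_rows([
        ("chr1", 0, 20_000, 2.0, "B-selected"),
        ("chr1", 10_000, 30_000, 2.5, "B-selected"),
        ("chr1", 60_000, 80_000, 3.0, "B-selected"),
    ])
    regions = merge_regions(scan)
    assert [(r.start, r.end, r.n_windows) for r in regions] == \
        [(0, 30_000, 2), (60_000, 80_000, 1)]
    assert regions[0].min_z == 2.0 and regions[0].max_z == 2.5


def test_merge_regions_opposite_directions_stay_apart():
    scan = _scan_rows([
        ("chr1", 0, 20_000, 2.0, "A-selected"),
        ("chr1", 10_000, 30_000, 2.0, "B-selected"),
    ])
    regions = merge_regions(scan)
    assert len(regions) == 2
    assert {r.direction for r in regions} == {"A-selected", "B-selected"}


def test_merge_regions_order_invariant_and_idempotent():
    rows = [("chr1", s, s + 20_000, 1.0, "B-selected")
            for s in (40_000, 0, 10_000, 80_000)] + \
           [("chr2", 0, 20_000, 1.0, "A-selected")]
    a = merge_regions(_scan_rows(rows))
    b = merge_regions(_scan_rows(rows[::-1]))
    assert [(r.chrom, r.start, r.end, r.direction) for r in a] == \
        [(r.chrom, r.start, r.end, r.direction) for r in b]
    # re-merging the merged regions (as 1-window rows) changes nothing
    again = merge_regions(_scan_rows(
        [(r.chrom, r.start, r.end, r.min_z, r.direction) for r in a]))
    assert [(r.chrom, r.start, r.end) for r in again] == \
        [(r.chrom, r.start, r.end) for r in a]


def _gene(gid, start, end, chrom="chr1", strand="+", **kw):
    return GeneModel(gid, chrom, strand, start, end, **kw)


def test_genes_in_regions_overlap_rule():
    from sweepscan.sweep import SweepRegion

    region = SweepRegion("chr1", 0, 30_000, "B-selected", 3, 1.0, 2.0)
    genes = [_gene("in", 5_000, 8_000), _gene("out", 30_001, 35_000),
             _gene("edge", 30_000, 35_000), _gene("other", 5_000, 8_000, chrom="chr2")]
    (got,) = genes_in_regions([region], genes)
    assert "in" in got.genes and "out" not in got.genes
    assert "other" not in got.genes
    assert "edge" in got.genes            # 1-based 30000 is the region's last base


def test_genes_in_regions_counts_tiled_genes():
    from sweepscan.sweep import SweepRegion

    genes = [_gene(f"g{i}", i * 10_000 + 1, i * 10_000 + 3_000) for i in range(10)]
    region = SweepRegion("chr1", 0, 30_000, "B-selected", 1, 0.0, 0.0)
    (got,) = genes_in_regions([region], genes)
    assert got.genes == ["g0", "g1", "g2"]


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------
@pytest.fixture
def gene_models():
    g = _gene("gA", 1_000, 4_000,
              exons=[(1_000, 1_800), (2_600, 4_000)],
              cds=[(1_200, 1_800), (2_600, 3_600)],
              utr5=[(1_000, 1_199)], utr3=[(3_601, 4_000)])
    g2 = _gene("gB", 20_000, 22_000, strand="-")
    return [g, g2]


@pytest.mark.parametrize("pos,want", [
    (1_500, "exonic"),        # inside CDS
    (1_801, "splicing"),      # 1 bp into the intron after exon 1
    (2_599, "splicing"),      # 1 bp before exon 2, intronic side
    (1_100, "UTR5"),
    (3_800, "UTR3"),
    (2_200, "intronic"),
    (500, "upstream"),        # 500 bp 5' of the + strand gene
    (4_500, "downstream"),
    (22_500, "upstream"),     # 3' in coordinates but 5' of the - strand gene
    (19_500, "downstream"),
    (10_000, "intergenic"),   # >= 2 kb from every gene
])
def test_annotate_snps_categories(gene_models, pos, want):
    panel = build_panel([[0], [1]], pos=[pos])
    ann = annotate_snps(panel, gene_models)
    assert ann["category"].iloc[0] == want


def test_annotate_snps_gene_without_structure_is_exonic(gene_models):
    # gB has no exon/CDS children: its whole span counts as one exon
    panel = build_panel([[0], [1]], pos=[21_000])
    assert annotate_snps(panel, gene_models)["category"].iloc[0] == "exonic"


def test_annotation_tally_is_exhaustive(gene_models):
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(30_000, size=200, replace=False)) + 1
    panel = build_panel(rng.integers(0, 3, size=(4, 200)), pos=pos)
    ann = annotate_snps(panel, gene_models)
    tally = annotation_tally(ann)
    assert tally["count"].sum() == panel.n_sites
    assert tally["percent"].sum() == pytest.approx(100.0)


# ----------------------------------------------------------------------
# diagnostic markers
# ----------------------------------------------------------------------
def test_diagnostic_marker_strict_fixed_difference():
    panel = build_panel([[0, 0], [0, 1], [2, 2], [2, 0]],
                        groups=["A", "A", "B", "B"])
    markers = diagnostic_markers(panel, strict=True)
    assert [(m.chrom, m.pos) for m in markers] == [("chr1", 10)]
    assert (markers[0].allele_a, markers[0].allele_b) == ("A", "G")


def test_diagnostic_marker_heterozygote_disqualifies():
    panel = build_panel([[0], [1], [2], [2]], groups=["A", "A", "B", "B"])
    assert diagnostic_markers(panel, strict=True) == []


def test_diagnostic_marker_missingness_cap():
    dosage = np.array([[0], [0], [MISSING], [2], [2], [2]])
    panel = build_panel(dosage, groups=["A"] * 3 + ["B"] * 3)
    assert diagnostic_markers(panel, strict=True, max_miss=0.1) == []
    got = diagnostic_markers(panel, strict=True, max_miss=0.5)
    assert len(got) == 1 and got[0].call_rate_a == pytest.approx(2 / 3)


def test_diagnostic_marker_relaxed_mode():
    # freq diff 0.875 passes a 0.8 floor but is not a strict marker
    panel = build_panel([[0], [0], [0], [0], [2], [2], [2], [1]],
                        groups=["A"] * 4 + ["B"] * 4)
    assert diagnostic_markers(panel, strict=True) == []
    got = diagnostic_markers(panel, strict=False, min_freq_diff=0.8)
    assert len(got) == 1
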