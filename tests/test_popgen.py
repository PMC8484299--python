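"""Windowed diversity, Weir-Cockerham Fst, Tajima's D and LD statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_panel
from sweepscan.panel import MISSING
from sweepscan.popgen import (WindowSpec, genome_tajimas_d, ld_decay, ld_r2,
                              make_windows, site_pi, tajima_constants,
                              tajimas_d, windowed_fst, windowed_pi,
                              wc_fst_site)

# ----------------------------------------------------------------------
# windows
# ----------------------------------------------------------------------
@pytest.mark.parametrize("length,n_full,n_total,last", [
    (100_000, 9, 10, (90_000, 100_000)),   # full windows start at 0..80k
    (15_000, 0, 2, (10_000, 15_000)),      # both windows truncated
    (20_000, 1, 2, (10_000, 20_000)),      # exactly one full window
])
def test_make_windows_truncation(length, n_full, n_total, last):
    w = make_windows({"chr1": length}, WindowSpec(20_000, 10_000))
    assert len(w) == n_total
    full = (w["end"] - w["start"] == 20_000).sum()
    assert full == n_full
    assert tuple(w.iloc[-1][["start", "end"]]) == last
    assert (w["start"] < length).all()


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(10_000, 20_000)
    with pytest.raises(ValueError):
        WindowSpec(0, 0)


# ----------------------------------------------------------------------
# nucleotide diversity
# ----------------------------------------------------------------------
def test_site_pi_values():
    assert site_pi(0, 10) == 0.0                       # monomorphic
    assert site_pi(2, 4) == pytest.approx(2 / 3)       # 4 of 6 pairs differ
    assert site_pi(1, 2) == 1.0                        # the two alleles differ


def brute_force_windowed_pi(panel, group, windows):
    """Oracle: enumerate all haplotype pairs per site, count mismatches."""
    dos = panel.group_dosage(group)
    spans = (windows["end"] - windows["start"]).to_numpy(float)
    out = np.zeros(len(windows))
    for w, (chrom, start, end) in enumerate(windows.itertuples(index=False)):
        total = 0.0
        for j in range(panel.n_sites):
            if panel.chrom[j] != chrom or not (start < panel.pos[j] <= end):
                continue
            alleles = []
            for g in dos[:, j]:
                if g != MISSING:
                    alleles += [1] * g + [0] * (2 - g)
            n = len(alleles)
            if n < 2:
                continue
            diff = sum(alleles[x] != alleles[y]
                       for x in range(n) for y in range(x + 1, n))
            total += diff / (n * (n - 1) / 2)
        out[w] = total / spans[w]
    return out


def test_windowed_pi_single_site_worked_example():
    # one site with n=4, j=2 in a 10-kb window: (2/3) / 10000
    panel = build_panel([[2], [0]], groups=["A", "A"], pos=[500])
    windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
    assert windowed_pi(panel, "A", windows)[0] == pytest.approx(6.6667e-5, rel=1e-4)


def test_windowed_pi_empty_and_monomorphic_windows_are_zero():
    panel = build_panel([[0, 2], [0, 2]], groups=["A", "A"], pos=[100, 200])
    windows = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 10_000],
                            "end": [10_000, 20_000]})
    assert list(windowed_pi(panel, "A", windows)) == [0.0, 0.0]


def test_windowed_pi_matches_bruteforce_on_random_panels():
    rng = np.random.default_rng(7)
    for _ in range(5):
        dosage = rng.integers(0, 3, size=(8, 60))
        dosage[rng.random(dosage.shape) < 0.05] = MISSING
        panel = build_panel(dosage, pos=np.sort(rng.choice(5_000, 60, replace=False)) + 1)
        windows = make_windows({"chr1": 5_000}, WindowSpec(1_000, 500))
        got = windowed_pi(panel, "A", windows)
        want = brute_force_windowed_pi(panel, "A", windows)
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)


# ----------------------------------------------------------------------
# Weir-Cockerham Fst
# ----------------------------------------------------------------------
def wc_fst_anova(dos1, dos2):
    """Oracle: WC84 variance components via the nested allele-indicator ANOVA.

    Works on raw dosage vectors (no missing), r = 2 populations.
    c = MSG, b = (MSI - MSG) / 2, a = (MSP - MSI) / (2 n_c).
    """
    pops = [np.asarray(dos1, float), np.asarray(dos2, float)]
    n = [len(d) for d in pops]
    r = 2
    nsum = sum(n)
    grand = sum(d.sum() for d in pops) / (2 * nsum)
    ssg = ssi = ssp = 0.0
    for d, ni in zip(pops, n):
        pm = d.sum() / (2 * ni)
        for g in d:
            mean_ind = g / 2
            # within-individual SS over the two allele indicators
            ssg += (1 - mean_ind) ** 2 * g + mean_ind ** 2 * (2 - g) \
                if g in (0, 1, 2) else 0
            ssi += 2 * (mean_ind - pm) ** 2
        ssp += 2 * ni * (pm - grand) ** 2
    msg = ssg / nsum
    msi = ssi / (nsum - r)
    msp = ssp / (r - 1)
    nc = (nsum - sum(ni ** 2 for ni in n) / nsum) / (r - 1)
    c = msg
    b = (msi - msg) / 2
    a = (msp - msi) / (2 * nc)
    return a, b, c


def _summaries(dos):
    dos = np.asarray(dos, float)
    return len(dos), dos.sum() / (2 * len(dos)), (dos == 1).mean()


def test_wc_fst_hand_cases():
    # fixed difference, 2 diploids each, no hets: a=0.5, b=0, c=0 -> Fst 1
    a, b, c = wc_fst_site(2, 1.0, 0.0, 2, 0.0, 0.0)
    assert (a, b, c) == pytest.approx((0.5, 0.0, 0.0))
    assert a / (a + b + c) == 1.0
    # identical all-heterozygote populations: a=0, b=-0.25, c=0.5 -> Fst 0
    a, b, c = wc_fst_site(2, 0.5, 1.0, 2, 0.5, 1.0)
    assert (a, b, c) == pytest.approx((0.0, -0.25, 0.5))
    assert a / (a + b + c) == 0.0


def test_wc_fst_matches_anova_oracle():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n1, n2 = rng.integers(2, 15, size=2)
        d1 = rng.integers(0, 3, size=n1)
        d2 = rng.integers(0, 3, size=n2)
        want = wc_fst_anova(d1, d2)
        got = wc_fst_site(*_summaries(d1), *_summaries(d2))
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)


def test_windowed_fst_worked_cases():
    windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})
    fixed = build_panel([[2], [2], [0], [0]], groups=["A", "A", "B", "B"],
                        pos=[100])
    assert windowed_fst(fixed, windows)[0] == pytest.approx(1.0)
    mono = build_panel([[0], [0], [0], [0]], groups=["A", "A", "B", "B"],
                       pos=[100])
    assert np.isnan(windowed_fst(mono, windows)[0])


def test_windowed_fst_identical_groups_not_positive(drift_panel):
    # the same genotypes labelled as two groups show no differentiation
    panel, _, _ = drift_panel
    dup = np.vstack([panel.dosage, panel.dosage])
    groups = ["A"] * panel.n_samples + ["B"] * panel.n_samples
    twin = build_panel(dup, groups=groups, pos=panel.pos)
    windows = make_windows({"chr1": 200_000}, WindowSpec(20_000, 10_000))
    fst = windowed_fst(twin, windows)
    assert np.nanmax(fst) <= 1e-12


# ----------------------------------------------------------------------
# Tajima's D
# ----------------------------------------------------------------------
def tajima_oracle(S, pi_sum, n):
    """Independent Tajima (1989) evaluator using exact rational constants."""
    from fractions import Fraction as F

    a1 = sum(F(1, i) for i in range(1, n))
    a2 = sum(F(1, i * i) for i in range(1, n))
    b1 = F(n + 1, 3 * (n - 1))
    b2 = F(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - F(n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = float(e1 * S + e2 * S * (S - 1))
    return (pi_sum - float(S / a1)) / np.sqrt(var)


def test_tajimas_d_undefined_cases():
    assert np.isnan(tajimas_d(0, 0.0, 10).D)
    assert np.isnan(tajimas_d(3, 1.0, 3).D)


def test_tajimas_d_worked_example():
    # n=4, S=1, pi=2/3: a1=11/6, theta_W=6/11, e1 ~ 0.00551 -> D ~ 1.633
    res = tajimas_d(1, 2 / 3, 4)
    assert res.D == pytest.approx(1.633, abs=5e-4)
    assert tajima_constants(4)["e1"] == pytest.approx(0.00551, abs=5e-6)


def test_tajimas_d_zero_when_pi_equals_watterson():
    k = tajima_constants(12)
    assert tajimas_d(9, 9 / k["a1"], 12).D == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_matches_oracle_grid():
    rng = np.random.default_rng(5)
    for n in (4, 9, 25, 60):
        for S in (1, 7, 40, 100):
            pi = S * rng.random() * 2
            assert tajimas_d(S, pi, n).D == pytest.approx(
                tajima_oracle(S, pi, n), abs=1e-9)


# ----------------------------------------------------------------------
# linkage disequilibrium
# ----------------------------------------------------------------------
def test_ld_r2_perfect_correlation():
    x = np.array([0, 1, 2, 0, 2, 1])
    assert ld_r2(x, x) == pytest.approx(1.0)
    assert ld_r2(x, 2 - x) == pytest.approx(1.0)


def test_ld_r2_undefined_on_zero_variance():
    assert np.isnan(ld_r2(np.zeros(6), np.array([0, 1, 2, 0, 2, 1])))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 2), min_size=4, max_size=20),
       st.lists(st.integers(0, 2), min_size=4, max_size=20))
def test_ld_r2_symmetry_and_polarity(xs, ys):
    k = min(len(xs), len(ys))
    x, y = np.array(xs[:k]), np.array(ys[:k])
    ab, ba = ld_r2(x, y), ld_r2(y, x)
    flipped = ld_r2(2 - x, y)
    assert (np.isnan(ab) and np.isnan(ba)) or ab == pytest.approx(ba)
    assert (np.isnan(ab) and np.isnan(flipped)) or ab == pytest.approx(flipped)


def test_ld_r2_unlinked_sites_mean_near_sampling_floor():
    # E[r^2] between independent sites ~ 1/(n-1)
    rng = np.random.default_rng(17)
    n = 30
    vals = []
    for _ in range(4_000):
        p, q = rng.uniform(0.2, 0.8, size=2)
        x = rng.binomial(2, p, size=n)
        y = rng.binomial(2, q, size=n)
        r2 = ld_r2(x, y)
        if np.isfinite(r2):
            vals.append(r2)
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 1 / (n - 1)) < 3 * se


def test_ld_decay_single_snp_is_empty():
    panel = build_panel([[0], [1], [2], [1]], groups=["A"] * 4, pos=[100])
    curve = ld_decay(panel, "A")
    assert curve.bin_mid.size == 0 and np.isnan(curve.half_decay_distance)


def test_ld_decay_on_drift_panel_decreases(drift_panel):
    panel, _, params = drift_panel
    ga = panel.group_labels[0]
    curve = ld_decay(panel, ga, max_dist=100_000, bin_width=5_000)
    assert ((curve.mean_r2 >= 0) & (curve.mean_r2 <= 1)).all()
    assert np.all(np.diff(curve.bin_mid) > 0)
    # LD must be higher at short range than at long range
    assert curve.mean_r2[0] > curve.mean_r2[-3:].mean()
    from scipy.stats import spearmanr
    rho = spearmanr(curve.bin_mid, curve.mean_r2).statistic
    assert rho < 0


def test_ld_decay_group_label_symmetry(drift_panel):
    panel, _, _ = drift_panel
    ga, gb = panel.group_labels
    swapped = {s: (gb if g == ga else ga) for s, g in panel.groups.items()}
    import dataclasses
    twin = dataclasses.replace(panel, groups=swapped)
    c1 = ld_decay(panel, ga, max_dist=50_000, bin_width=5_000)
    c2 = ld_decay(twin, gb, max_dist=50_000, bin_width=5_000)
    np.testing.assert_allclose(c1.mean_r2, c2.mean_r2)


def test_genome_tajimas_d_drift_panel_defined(drift_panel):
    panel, _, _ = drift_panel
    for g in panel.group_labels:
        assert np.isfinite(genome_tajimas_d(panel, g).D)
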