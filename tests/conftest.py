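import numpy as np
import pytest

from sweepscan.panel import GenotypePanel


def build_panel(dosage, pos=None, chrom="chr1", groups=None, mq=None,
                depth=None):
    """Construct a small panel from a dosage matrix (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    samples = [f"s{i:02d}" for i in range(n)]
    if groups is None:
        half = (n + 1) // 2
        groups = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
    elif not isinstance(groups, dict):
        groups = {s: g for s, g in zip(samples, groups)}
    if pos is None:
        pos = (np.arange(m) + 1) * 10
    if mq is None:
        mq = np.full(m, 60.0)
    return GenotypePanel(
        samples=samples, groups=groups,
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        mq=np.asarray(mq, dtype=float),
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


@pytest.fixture
def panel_factory():
    return build_panel


@pytest.fixture(scope="session")
def drift_panel():
    """A small two-population drift simulation shared across tests."""
    from sweepscan.simulate import SimParams, simulate_panel

    params = SimParams(seed=11, n_diploid=60, generations=60, length=200_000,
                       n_sites=1_000, sel_coef=0.0, sweep_pos=100_000,
                       p0_sweep=0.0, n_sample_a=10, n_sample_b=10)
    panel, truth = simulate_panel(params)
    return panel, truth, params


def write_vcf_text(path, records, samples, fmt="GT:DP"):
    """Write a minimal VCF from (chrom, pos, ref, alt, info, calls) tuples."""
    lines = ["##fileformat=VCFv4.2",
             "##contig=<ID=chr1>",
             '##INFO=<ID=MQ,Number=1,Type=Float,Description="x">',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    for chrom, pos, ref, alt, info, calls in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\t{fmt}\t"
                     + "\t".join(calls))
    path.write_text("\n".join(lines) + "\n")
    return path
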