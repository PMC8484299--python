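"""Forward Wright-Fisher simulator for two-population SNP panels.

The simulator emulates the statistical structure the scan assumes: two
diploid populations of N individuals split from a common ancestral pool
and drift apart for t generations, with an optional beneficial allele
under directional selection in population B only (multiplicative
fitness 1, 1+s, (1+s)^2).  Variation is standing at t=0 — site
frequencies are drawn from the neutral site-frequency-spectrum density
proportional to 1/x and haplotypes are drawn site-wise Bernoulli
(linkage equilibrium), and no new mutations arise during the forward
phase — so the site set is fixed and ground truth is exact.  Gametes
recombine with a Poisson(r*L) number of crossovers at uniform
positions.

The beneficial allele is modelled as a recent single-origin variant:
the p0 fraction of haplotypes that carry it (in both populations) are
copies of one founder haplotype, so selection in B drives a hard sweep
that erases diversity near the locus, while recombination — the
default rate gives about one crossover per meiosis on the toy
chromosome, i.e. a chromosome-scale genetic map compressed onto 1 Mb —
restores diversity away from it.  This yields the classic localized
signature (elevated Fst, depressed diversity around the locus) that
the scan is built to detect.

Sampling draws n diploids per population (defaults mirror a 13 + 12
two-group resequencing panel), synthesizes per-genotype depths
(Poisson, mean 14) and a site RMS mapping quality of 60, and writes a
VCF, a group table, a ground-truth TSV, a toy GFF3 gene tiling and a
run manifest.  Everything is a pure function of (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import GenotypePanel
from .popgen import WindowSpec
from .variant_io import write_group_table, write_vcf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; ``seed`` is required, everything else defaulted.

    Attributes
    ----------
    n_diploid : diploid individuals per population (N).
    generations : generations since the populations split (t).
    length : chromosome length in bp (L).
    n_sites : segregating sites at initialization (m).
    recomb_rate : per-bp per-generation recombination rate (r); the
        default gives r*L = 1 expected crossover per meiosis on the toy
        chromosome.
    sel_coef : per-allele selection coefficient s acting in population
        B only (fitness 1, 1+s, (1+s)^2 by beneficial-allele dosage).
    sweep_pos : bp position of the selected site.
    p0_sweep : initial beneficial-allele frequency in both populations;
        carriers share a single founder haplotype (single origin).
    n_sample_a / n_sample_b : diploids sampled per group for the panel.
    mean_depth : mean of the synthesized per-genotype Poisson depth.
    lowq_rate : fraction of sites written with injected quality
        violations (low MQ or out-of-bounds DP) to exercise filters.
    n_fixed_diff : engineered fixed-difference sites (marker truth).
    """

    seed: int
    n_diploid: int = 200
    generations: int = 200
    length: int = 1_000_000
    n_sites: int = 5_000
    recomb_rate: float = 2e-6
    sel_coef: float = 0.2
    sweep_pos: int = 505_000
    p0_sweep: float = 0.05
    n_sample_a: int = 12
    n_sample_b: int = 13
    mean_depth: float = 14.0
    group_a: str = "CO"
    group_b: str = "VO"
    chrom: str = "chr1"
    n_fixed_diff: int = 0
    lowq_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0_sweep <= 1.0):
            raise ValueError("p0_sweep must be in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_sites > self.length:
            raise ValueError(f"n_sites {self.n_sites} exceeds length {self.length}")
        if not (1 <= self.sweep_pos <= self.length):
            raise ValueError("sweep_pos must lie within [1, length]")
        if self.n_sample_a > self.n_diploid or self.n_sample_b > self.n_diploid:
            raise ValueError("cannot sample more diploids than the population holds")
        if self.generations < 0 or self.n_diploid < 2:
            raise ValueError("need generations >= 0 and n_diploid >= 2")


@dataclass
class Pool:
    """Haplotype pools of the two populations (rows = 2N haplotypes)."""

    positions: np.ndarray        # (m,) sorted 1-based bp
    init_freq: np.ndarray        # (m,) ancestral allele-1 frequencies
    hap_a: np.ndarray            # (2N, m) uint8
    hap_b: np.ndarray
    sweep_idx: int


@dataclass
class SimTruth:
    """Ground truth recorded by the simulator for recovery tests."""

    params: SimParams
    positions: np.ndarray
    freq_a: np.ndarray           # final allele-1 frequency, population A
    freq_b: np.ndarray
    sweep_pos: int
    sweep_idx: int
    sweep_freq_a: float
    sweep_freq_b: float
    fixed_diff_positions: list[int] = field(default_factory=list)
    segregating_positions: np.ndarray | None = None  # sites written to the VCF

    @property
    def n_segregating(self) -> int:
        return 0 if self.segregating_positions is None else len(self.segregating_positions)

    def sweep_windows(self, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
        """0-based half-open scan windows containing the sweep position."""
        out = []
        start = 0
        while start < self.params.length:
            end = min(start + spec.size, self.params.length)
            if start < self.sweep_pos <= end:
                out.append((start, end))
            start += spec.step
        return out


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------
def init_population(params: SimParams, rng: np.random.Generator | None = None) -> Pool:
    """Draw the ancestral standing variation and both population pools.

    Site positions are uniform without replacement on [1, L]; ancestral
    frequencies follow the neutral SFS density 1/x truncated to
    [1/(2N), 1 - 1/(2N)]; non-carrier haplotypes are site-wise
    Bernoulli draws (linkage equilibrium at t=0).  The site nearest
    ``sweep_pos`` is moved to exactly ``sweep_pos`` and its frequency
    overridden to ``p0_sweep`` in both populations; beneficial-allele
    carriers are copies of a single founder haplotype, emulating a
    recent single-origin variant standing at frequency p0.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m, two_n = params.n_sites, 2 * params.n_diploid

    positions = np.sort(rng.choice(params.length, size=m, replace=False)) + 1
    lo, hi = 1.0 / two_n, 1.0 - 1.0 / two_n
    u = rng.random(m)
    freq = lo * (hi / lo) ** u          # inverse-CDF of density 1/x on [lo, hi]

    sweep_idx = int(np.argmin(np.abs(positions - params.sweep_pos)))
    positions[sweep_idx] = params.sweep_pos
    if len(np.unique(positions)) != m:          # nearest neighbour collided
        keep = np.ones(m, dtype=bool)
        dup = np.flatnonzero(positions == params.sweep_pos)
        keep[dup[dup != sweep_idx]] = False
        positions, freq = positions[keep], freq[keep]
        sweep_idx = int(np.flatnonzero(positions == params.sweep_pos)[0])
    order = np.argsort(positions, kind="stable")
    positions, freq = positions[order], freq[order]
    sweep_idx = int(np.flatnonzero(positions == params.sweep_pos)[0])
    freq[sweep_idx] = params.p0_sweep

    hap_a = (rng.random((two_n, len(positions))) < freq).astype(np.uint8)
    hap_b = (rng.random((two_n, len(positions))) < freq).astype(np.uint8)
    hap_a[:, sweep_idx] = 0
    hap_b[:, sweep_idx] = 0
    if params.p0_sweep > 0:
        founder = (rng.random(len(positions)) < freq).astype(np.uint8)
        founder[sweep_idx] = 1
        carriers_a = rng.random(two_n) < params.p0_sweep
        carriers_b = rng.random(two_n) < params.p0_sweep
        hap_a[carriers_a] = founder
        hap_b[carriers_b] = founder
    return Pool(positions, freq, hap_a, hap_b, sweep_idx)


# ----------------------------------------------------------------------
# forward evolution
# ----------------------------------------------------------------------
def _next_generation(
    haps: np.ndarray,
    positions: np.ndarray,
    fitness: np.ndarray | None,
    crossover_mean: float,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation for a (2N, m) haplotype pool."""
    n = haps.shape[0] // 2
    if fitness is None:
        parents = rng.integers(0, n, size=(n, 2))
    else:
        prob = fitness / fitness.sum()
        parents = rng.choice(n, size=(n, 2), p=prob)
    coin = rng.integers(0, 2, size=(n, 2))
    n_cross = rng.poisson(crossover_mean, size=(n, 2))

    new = haps[(2 * parents + coin).reshape(-1)].copy()
    for j, g in zip(*np.nonzero(n_cross)):
        bps = np.sort(rng.integers(1, length + 1, size=n_cross[j, g]))
        seg = np.searchsorted(bps, positions, side="left")
        which = (coin[j, g] + seg) % 2
        p = parents[j, g]
        new[2 * j + g] = np.where(which == coin[j, g] % 2,
                                  haps[2 * p + coin[j, g]],
                                  haps[2 * p + 1 - coin[j, g]])
    return new


def evolve(pool: Pool, params: SimParams, rng: np.random.Generator | None = None) -> SimTruth:
    """Run t generations of drift/selection/recombination in place.

    Selection acts only in population B, at the sweep site, with
    multiplicative fitness (1+s) per beneficial allele.  Offspring draw
    two parents with probability proportional to fitness; each gamete
    carries Poisson(r*L) crossovers at uniform positions.  No new
    mutations arise.  Returns the ground truth with final frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    crossover_mean = params.recomb_rate * params.length
    for _ in range(params.generations):
        pool.hap_a = _next_generation(pool.hap_a, pool.positions, None,
                                      crossover_mean, params.length, rng)
        if params.sel_coef != 0.0:
            dosage = (pool.hap_b[0::2, pool.sweep_idx]
                      + pool.hap_b[1::2, pool.sweep_idx]).astype(float)
            fitness = (1.0 + params.sel_coef) ** dosage
        else:
            fitness = None
        pool.hap_b = _next_generation(pool.hap_b, pool.positions, fitness,
                                      crossover_mean, params.length, rng)

    freq_a = pool.hap_a.mean(axis=0)
    freq_b = pool.hap_b.mean(axis=0)
    truth = SimTruth(
        params=params, positions=pool.positions.copy(),
        freq_a=freq_a, freq_b=freq_b,
        sweep_pos=int(pool.positions[pool.sweep_idx]), sweep_idx=pool.sweep_idx,
        sweep_freq_a=float(freq_a[pool.sweep_idx]),
        sweep_freq_b=float(freq_b[pool.sweep_idx]),
    )
    return truth


def _engineer_fixed_differences(pool: Pool, params: SimParams, truth: SimTruth) -> None:
    """Force ``n_fixed_diff`` sites to opposite fixation in A and B.

    Sites are picked deterministically, spread over the chromosome and
    away from the sweep site, then overwritten after evolution so the
    marker screen has an exact truth set.
    """
    if params.n_fixed_diff == 0:
        return
    m = len(pool.positions)
    targets = []
    for k in range(params.n_fixed_diff):
        want = (k + 1) * params.length // (params.n_fixed_diff + 3)
        idx = int(np.argmin(np.abs(pool.positions - want)))
        while idx in targets or idx == pool.sweep_idx:
            idx = (idx + 1) % m
        targets.append(idx)
    for idx in targets:
        pool.hap_a[:, idx] = 0
        pool.hap_b[:, idx] = 1
        truth.freq_a[idx] = 0.0
        truth.freq_b[idx] = 1.0
    truth.fixed_diff_positions = [int(pool.positions[i]) for i in targets]


# ----------------------------------------------------------------------
# sampling and output
# ----------------------------------------------------------------------
_REF_ALT = ("A", "G")   # arbitrary fixed alleles; allele 1 is the alt


def sample_panel(
    pool: Pool, params: SimParams, truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> GenotypePanel:
    """Sample n diploids per population into a genotype panel.

    Sites monomorphic across all sampled genotypes are dropped (a real
    variant caller only reports segregating sites); the surviving
    positions are recorded in the truth.  Per-genotype depths are
    Poisson(mean_depth), site MQ is 60; when ``lowq_rate`` > 0 that
    fraction of sites gets an injected violation (alternating low MQ
    and out-of-bounds DP).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    _engineer_fixed_differences(pool, params, truth)

    idx_a = np.sort(rng.choice(params.n_diploid, size=params.n_sample_a, replace=False))
    idx_b = np.sort(rng.choice(params.n_diploid, size=params.n_sample_b, replace=False))
    dos_a = pool.hap_a[2 * idx_a] + pool.hap_a[2 * idx_a + 1]
    dos_b = pool.hap_b[2 * idx_b] + pool.hap_b[2 * idx_b + 1]
    dosage = np.vstack([dos_a, dos_b]).astype(np.int8)

    seg = (dosage.sum(axis=0) > 0) & (dosage.sum(axis=0) < 2 * dosage.shape[0])
    dosage = dosage[:, seg]
    positions = pool.positions[seg]
    truth.segregating_positions = positions.copy()
    m = len(positions)

    samples = ([f"{params.group_a}{i + 1:02d}" for i in range(params.n_sample_a)]
               + [f"{params.group_b}{i + 1:02d}" for i in range(params.n_sample_b)])
    groups = {s: (params.group_a if i < params.n_sample_a else params.group_b)
              for i, s in enumerate(samples)}

    depth = rng.poisson(params.mean_depth, size=dosage.shape).astype(np.int32)
    mq = np.full(m, 60.0)
    if params.lowq_rate > 0:
        n_bad = int(round(params.lowq_rate * m))
        bad = rng.choice(m, size=n_bad, replace=False)
        for k, j in enumerate(np.sort(bad)):
            if k % 2 == 0:
                mq[j] = 10.0
            else:
                depth[::2, j] = 1          # depth floor violated in half the calls
    logger.info("sample_panel: %d samples x %d segregating sites", len(samples), m)
    return GenotypePanel(
        samples=samples, groups=groups,
        chrom=np.full(m, params.chrom, dtype=object),
        pos=positions.astype(np.int64),
        ref=np.full(m, _REF_ALT[0], dtype=object),
        alt=np.full(m, _REF_ALT[1], dtype=object),
        mq=mq, dosage=dosage, depth=depth,
    )


def simulate_panel(params: SimParams) -> tuple[GenotypePanel, SimTruth]:
    """Full in-memory run: initialize, evolve, sample."""
    rng = np.random.default_rng(params.seed)
    pool = init_population(params, rng)
    truth = evolve(pool, params, rng)
    panel = sample_panel(pool, params, truth, rng)
    return panel, truth


# ----------------------------------------------------------------------
# files
# ----------------------------------------------------------------------
GENE_SIZE = 3_000
GENE_EVERY = 10_000


def write_toy_gff3(length: int, chrom: str, path: str | Path) -> int:
    """Tile 3-kb two-exon genes every 10 kb; returns the gene count.

    Each gene has a 1-kb exon at either end and a 1-kb intron between,
    with CDS matching the exons, so every annotation category is
    reachable.  Strands alternate.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        start = 1
        while start + GENE_SIZE - 1 <= length:
            end = start + GENE_SIZE - 1
            gid = f"gene{n:05d}"
            strand = "+" if n % 2 == 0 else "-"
            exon1 = (start, start + 999)
            exon2 = (end - 999, end)
            fh.write(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n")
            fh.write(f"{chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={gid}.t1;Parent={gid}\n")
            for i, (s, e) in enumerate((exon1, exon2), 1):
                fh.write(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                         f"ID={gid}.t1.exon{i};Parent={gid}.t1\n")
                fh.write(f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                         f"ID={gid}.t1.cds{i};Parent={gid}.t1\n")
            n += 1
            start += GENE_EVERY
    return n


def write_truth(truth: SimTruth, path: str | Path) -> None:
    seg = set() if truth.segregating_positions is None else set(
        int(p) for p in truth.segregating_positions)
    fixed = set(truth.fixed_diff_positions)
    with open(path, "w") as fh:
        fh.write("pos\tfreq_a\tfreq_b\tis_sweep\tis_fixed_diff\tin_vcf\n")
        for j, pos in enumerate(truth.positions):
            fh.write(f"{int(pos)}\t{truth.freq_a[j]:.6f}\t{truth.freq_b[j]:.6f}\t"
                     f"{int(j == truth.sweep_idx)}\t{int(int(pos) in fixed)}\t"
                     f"{int(int(pos) in seg)}\n")


def sample_and_write(
    params: SimParams,
    out_prefix: str | Path,
    window_spec: WindowSpec = WindowSpec(),
) -> dict[str, Path]:
    """Run the simulator and write VCF + group table + truth + GFF3 + manifest.

    Returns a dict of output paths keyed by kind.  Byte-identical
    output for identical (params, seed).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(params)

    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "groups": Path(f"{prefix}.groups.tsv"),
        "truth": Path(f"{prefix}.truth.tsv"),
        "gff3": Path(f"{prefix}.genes.gff3"),
        "manifest": Path(f"{prefix}.manifest.json"),
    }
    write_vcf(panel, paths["vcf"])
    write_group_table(panel.groups, paths["groups"])
    write_truth(truth, paths["truth"])
    n_genes = write_toy_gff3(params.length, params.chrom, paths["gff3"])
    manifest = {
        "params": dataclasses.asdict(params),
        "n_genes": n_genes,
        "n_segregating": truth.n_segregating,
        "sweep_pos": truth.sweep_pos,
        "sweep_freq_a": truth.sweep_freq_a,
        "sweep_freq_b": truth.sweep_freq_b,
        "fixed_diff_positions": truth.fixed_diff_positions,
        "sweep_windows": truth.sweep_windows(window_spec),
        "window_spec": {"size": window_spec.size, "step": window_spec.step},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
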