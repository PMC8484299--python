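# Methods

## Statistics

**Nucleotide diversity.** Per site, θπ is the unbiased mean pairwise
difference 2j(n−j)/(n(n−1)) for j alternate alleles among n called
alleles; windows sum per-site values and divide by the window span in
bp (truncated terminal windows divide by their actual span), so values
are per-bp and comparable across windows.  Sites with fewer than two
called alleles contribute nothing.

**F<sub>ST</sub>.** Weir & Cockerham's (1984) two-population variance
components a (among populations), b (among individuals within
populations) and c (within individuals) are computed per site from the
called-diploid counts n_i, alternate-allele frequencies p_i and
observed heterozygote frequencies h_i.  A window's estimate is the
ratio of sums Σa / Σ(a+b+c); sites where either group has fewer than
two called diploids, or where the denominator is zero (monomorphic
across both groups), contribute nothing.  Negative estimates are
reported, not clamped — they are the estimator's rendering of "no
differentiation", and clamping would bias window means upward.  The
test suite checks the implementation against an independent evaluator
that computes the same components through the nested allele-indicator
ANOVA (mean squares MSP/MSI/MSG) rather than the closed-form
expressions.

**Tajima's D.** Computed from S segregating sites, the summed per-site
pairwise diversity π̂, and the allele count n, with the 1989 constants
a1…e2.  Windowed values use the nominal n = 2 × (group sample count)
while π̂ and S come from called alleles; with missingness capped at 10%
by the site filters this approximation is bounded and documented
rather than corrected.  D is undefined (NaN) when S = 0 or n < 4.

**LD.** r² is the squared Pearson correlation of unphased genotype
dosages over pairwise-complete samples (no haplotype phasing or EM).
The decay curve averages r² in distance bins over all intra-chromosome
pairs within 5 Mb whose MAFs are ≥ 0.05; the half-decay distance is
the smallest bin midpoint whose mean r² is at most half the maximum
bin mean.  This operational definition is a package choice — "LD decay
distance" has no single standard definition.

**Sweep scan.** Window F<sub>ST</sub> values are standardized over
eligible windows (Z-transform with the sample SD); the diversity
contrast is log₂(θπ_A/θπ_B) with group A the reference (numerator)
group.  Eligibility requires a defined F<sub>ST</sub>, θπ > 0 in both
groups and at least 10 SNPs; exclusion (rather than ±∞ ratios) is the
package's choice for empty or monomorphic windows, and both floors are
configurable.  Thresholds are empirical order-statistic quantiles
(numpy's default type-7 interpolation) computed over eligible windows,
per tail, with ties at the threshold included (≥/≤).  B-selected
windows satisfy Z(F<sub>ST</sub>) ≥ the (1−q) quantile **and** ratio ≥
the (1−q) quantile; A-selected windows pair the same Z threshold with
ratio ≤ the q quantile.  Same-direction outlier windows that overlap
or abut merge into regions; genes overlap a region when their span
(not CDS only) shares ≥ 1 bp with it, with the region's 0-based
half-open bounds converted to the gene's 1-based inclusive coordinates
exactly, so a gene starting on the region's last covered base counts.

**Structure.** The distance is the allele-sharing p-distance
d(i,j) = 1 − Σ(2 − |g_i − g_j|)/(2m_ij) over pairwise-complete sites.
Neighbor joining runs on this matrix (scikit-bio's implementation);
negative branch lengths, a known NJ artifact, are clamped to zero and
the clamp count logged.  The GRM is the single-component form
G(i,j) = (1/m) Σ_k (x_ik−2p_k)(x_jk−2p_k)/(2p_k(1−p_k)) over
polymorphic sites with missing dosages mean-imputed to 2p_k; PCA is
its eigendecomposition, with each eigenvector's sign fixed so the
largest-magnitude loading is positive (determinism).  No LD pruning is
applied before PCA.

## Filters

Depth bounds are applied **per genotype** (FORMAT/DP): a failing
genotype becomes missing instead of discarding the whole site, which
matches the magnitude of the 3–50 bounds at ~14× mean depth.  MAF is
computed over called alleles only.  Site removal is attributed to the
first failing rule in the order mq → maf → miss, so tallies are
deterministic and sum exactly; sites whose mapping quality is absent
pass the mq rule (quality unknown, not low).  A site with no called
alleles has no defined MAF and is removed under the maf rule by this
ordering.  The genotype-then-site filter pair is idempotent.

## The simulator

Two diploid Wright–Fisher populations of N individuals split from a
common ancestral pool and evolve independently for t generations.
Standing variation only: m site positions are uniform on [1, L],
ancestral frequencies follow the neutral SFS density ∝ 1/x truncated
to [1/2N, 1−1/2N], haplotypes are site-wise Bernoulli draws, and no
new mutations arise — the fixed site set makes truth bookkeeping and
VCF emission exact.  Gametes carry Poisson(rL) crossovers at uniform
positions.  Selection acts only in population B, at one locus, with
multiplicative fitness (1+s) per beneficial allele.

The beneficial allele is modelled as a **recent single-origin
variant**: the p0 fraction of haplotypes carrying it (in both
populations) are copies of one founder haplotype.  This matters: with
carriers on independent backgrounds (linkage equilibrium at the
locus), a sweep from p0 = 0.05 is soft — it *raises* diversity near
the locus by lifting rare variants to intermediate frequency — and
produces no localized signature for the scan to find.  The
single-origin design gives the classic hard-sweep footprint: diversity
erased near the locus in B, elevated F<sub>ST</sub> against A, and
recovery with distance as recombination during the ~30-generation
sweep reintroduces non-carrier material.

Defaults (one run ≈ 5 s): N = 200 diploids per population, t = 200
generations, L = 1 Mb, m = 5,000 sites, s = 0.2, p0 = 0.05, sample
sizes 12 + 13 diploids, synthesized per-genotype depth ~ Poisson(14)
and site MQ 60.  The recombination rate default is r = 2×10⁻⁶ per bp
per generation — deliberately a *chromosome-scale genetic map
compressed onto 1 Mb* (rL ≈ 1 crossover per meiosis, as for a real
~50-cM chromosome) rather than a literal per-bp rate, chosen so the
hitchhiking scale 1/(r·τ_sweep) ≈ 17 kb matches the 20-kb scan window;
without this compression the whole toy chromosome is one linked block
and nothing localizes.  The sweep locus default (505,000 bp) sits
off the 10-kb window grid so its signature is not split across a
window boundary.  An optional engineered fixed-difference site
(opposite fixation in A and B, positions recorded in the truth table)
supports exact marker-screen tests, and an optional low-quality
injection rate writes sites violating the MQ or DP filters to exercise
the filter tallies.

What the generator does **not** emulate: new mutation during the
forward phase (so diversity only decays; genome-wide Tajima's D is
positive by construction), coalescent-realistic background LD at t=0
(LD is generated by drift during the run), sequencing/genotyping error
beyond the injected violations, depth variation between samples,
multiple chromosomes, and any gene-function structure (the GFF3 is a
uniform tiling of 3-kb two-exon genes every 10 kb).  Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under drift + hard selection, not that the
pipeline is robust to real-data artifacts such as mapping bias or
batch effects.

## Calibration and known limitations

The validation suite measures, per seed: mean windowed
F<sub>ST</sub> ≈ 0 (|mean| < 0.01) with ≤ 5% outliers per direction
when the two groups are drawn from one pool; mean windowed
F<sub>ST</sub> within [0.25, 0.55] after t = 100 generations at
N = 100, bracketing the drift expectation 1 − e^(−t/2N) = 0.39; and
perfect (Rand index 1.0) recovery of the group labels by both the NJ
bipartition and the PC1 sign split at that drift level.

The joint top-5% sweep call has limited per-seed power at the default
toy scale, and `scripts/acceptance.py` reports it honestly (detection
rate ~70%, diversity-depression rate ~100% over ten seeds).  Three
causes, all intrinsic to a 1-Mb genome: (i) 99 windows put the
empirical 95th percentile at the 5th-largest value, so the sweep's own
3–6-window signature competes with itself for the threshold; (ii) the
drift background (t/2N = 0.5) gives window-F<sub>ST</sub> spread of
the same order as a single window's sweep boost; (iii) in the
strongest sweeps θπ_B reaches exactly 0 in the containing windows,
which the eligibility rule then excludes from calling.  At
genome-scale window counts (tens of thousands) the first effect
vanishes; users scanning small regions should interpret per-window
calls accordingly and prefer the merged-region view.

## Conventions

Windows are 0-based half-open internally; file outputs follow each
format's convention (VCF 1-based, BED 0-based half-open).  All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical (config, seed) runs produce
byte-identical outputs, and `--threads` never affects results.
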