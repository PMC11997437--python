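# Methods

This note records the statistical models, algorithmic choices and
known limitations behind `panelsmith`, in the order the pipeline runs.

## Genotype model and coordinates

All analyses work from unphased diploid genotype codes
{0 hom-ref, 1 het, 2 hom-alt, −1 missing} on biallelic SNPs;
multiallelic and indel records are dropped at VCF ingest. Internal
coordinates are 1-based (VCF convention); BED output converts to
0-based half-open at the boundary. Nothing downstream uses phase, so
phased and unphased GT fields are treated identically and half-missing
genotypes (`./1`) become missing. Missing genotypes are excluded from
allele counts everywhere — no imputation.

## Per-site statistics and the inclusion filter

For a site with allele frequency p (alt) and q = 1−p estimated from
called genotypes (a het contributes one allele of each kind):

* MAF = min(p, q); expected heterozygosity H_e = 2pq;
* classical PIC = 1 − p² − q² − 2p²q² (maximum 0.375 at MAF 0.5);
* chip PIC ≡ H_e (maximum 0.5).

Two PIC flavours are reported because the informativeness band that a
MAF > 0.35 filter produces — (0.455, 0.5] — is only attainable by the
H_e form; the classical form saturates at 0.375. Panel scoring uses
chip PIC; both columns appear in every report.

The inclusion filter is `missing < 0.1 AND maf > 0.35 AND hobs < 0.5`,
all strict. The missing-rate comparison is implemented on the
call-rate side (`call_rate > 1 − max_missing`) because `1 − 0.9 < 0.1`
is true in binary floating point and would silently soften the strict
boundary.

## Probe evaluation

Each candidate's left and right 110-bp flanks are evaluated
independently: both must have GC ∈ [0.3, 0.7] (closed band; N bases
count in the denominator only), and flanks truncated by a contig edge
fail outright. "110-bp flanking sequence" is read as each flank
separately — capture baits tile both sides of a target — with a
`mode="centered"` switch for the single-window reading.

### Homology specificity

A genomic region is homologous to a probe when an ungapped alignment
window satisfies any of (strict thresholds):

| rule | window | minimum matches |
|------|--------|-----------------|
| identical run > 40 bp | 41 | 41/41 |
| > 85% over 80 bp      | 80 | 69/80 |
| > 95% over 70 bp      | 70 | 67/70 |

Both the probe and its reverse complement are scanned against every
contig, so the search is strand-symmetric. The scan is exact:

1. **Complete seeding.** Any qualifying window contains an exact 6-mer
   shared with the probe (pigeonhole: 11 mismatches cut an 80-bp
   window into 12 runs summing to ≥ 69 bases, so the longest run is
   ≥ 6; the other rules force longer runs). A sorted 6-mer index per
   contig (built once, cached on the genome object) yields every
   candidate alignment diagonal.
2. **Exhaustive verification.** Each candidate diagonal is walked with
   prefix-summed match counts and all three rule windows are tested at
   every offset (numba kernel). Qualifying windows mark a per-position
   coverage mask.
3. **Region merging.** Covered runs closer than 10 bp are merged into
   maximal regions — the specificity criterion counts *regions*, not
   alignments — and regions overlapping the probe's own source locus
   (± flank length around the SNP) are discarded. Hits from the two
   flanks are pooled and re-merged before counting.

A site passes specificity when the merged region count is strictly
below 5. The test suite checks the scan against a brute-force
all-offset, both-strand oracle on small genomes with planted
approximate repeats; agreement is exact, which is why seeding is an
optimization rather than a semantic choice. Gapped homology is not
modelled: the three rules are fixed-window identity rules, and an
indel-containing alignment that satisfies none of them is not a hit.

## Uniform selection

Chromosomes are partitioned into fixed, non-overlapping windows
anchored at position 0 (window 100 kb by default; the paper-scale
default, scaled down in examples to match simulated genome sizes). At
most one candidate per window is kept: highest chip PIC, ties broken
by proximity to the window centre, then lowest position — fully
deterministic, so reruns are bit-identical. One-per-window is a
recorded default; real designs sometimes admit more loci where density
allows.

Panel metrics: adjacent distances within chromosomes only; distance
fractions use closed upper bounds (≤ 10 kb, ≤ 20 kb); the SNP-count vs
chromosome-length Pearson r carries a two-sided t-test p-value and is
NaN (flagged) for fewer than two usable chromosomes.

## Population-genetic estimators

* **π** per site is c_ref·c_alt / C(n, 2) over called alleles —
  identical to the mean pairwise difference, verified by enumeration.
  Windowed π divides the sum of site values by the window length in
  bp (empty windows report 0 but are excluded from concordance
  correlations); fragment π restricts the same estimator to capture
  fragments.
* **F_ST** is Weir & Cockerham (1984) with per-site variance
  components a (among-population), b, c computed from per-population
  sample sizes, allele frequencies and het fractions; windows and the
  genome-wide value are Σa / Σ(a+b+c) (ratio of sums). Negative
  estimates are reported, not clipped. Sites monomorphic overall
  contribute nothing; a window where some population is entirely
  missing is flagged NaN. Note the estimator's finite-sample behaviour:
  two groups with *identical* genotype vectors give a small negative
  value of order −1/(2n), not exactly 0.
* **Tajima's D** uses the standard a₁…e₂ constants with
  θ_π = Σ site π (counts) and θ_W = S/a₁. Each diploid contributes two
  alleles; under missingness n is the minimum called allele count
  across segregating sites (conservative). S = 0 returns NaN.
* **Concordance** between two windowed analyses is Pearson r over
  windows matched on coordinates, excluding windows empty in either.

On Balding–Nichols simulations the genome-wide F_ST recovers the
generating F within Monte-Carlo error, and a MAF > 0.35 subset agrees
with the all-site estimate to well under 0.01 at F ≈ 0.04 — the
chip-vs-resequencing consistency pattern — while fragment π is
inflated relative to genome-wide π, as expected when rare variants are
excluded by design.

## Fingerprinting and IBD

**Distillation.** k = 384 loci are allocated to chromosomes
proportionally to length (largest-remainder rounding) and chosen
greedily by chip PIC under a minimum-spacing constraint; shortfalls
are refilled best-effort from other chromosomes with a warning. The
procedure is deliberately simple and deterministic; it is exposed so
alternative strategies can replace it.

**QR profiles.** Genotypes map to 2-bit codes (00/01/10/11 =
hom-ref/het/hom-alt/missing), laid out row-major over 32 columns with
zero padding, plus one column-parity (XOR) row. Decoding re-checks
parity, so any single flipped cell is detected (an even number of
flips in one column is not — this is an integrity check, not an
error-correcting code). The scheme is versioned in the JSON payload.

**IBD.** Method-of-moments: observed IBS counts (IBS = 2 − |g_A −
g_B|) over informative loci (non-missing in both samples, cohort
MAF ≥ 0.01) are combined with Σ P(IBS | IBD) expectations — functions
of cohort allele frequencies with small-sample correction factors
driven by the number of frequency-estimating alleles — and solved
sequentially for Z0, Z1, Z2. Raw solutions satisfy Z0+Z1+Z2 = 1 and
are unbiased (verified by simulation: mean raw π̂ ≈ 0.002, SD 0.063
for unrelated pairs at 384 loci). Estimates are then bounded to [0, 1]
and renormalized, which floors π̂ at 0 and induces a positive mean of
≈ +0.05 for truly unrelated pairs at 384 high-MAF loci; this is an
inherent cost of bounding at small locus counts, shrinking as loci are
added, and is harmless for classification (the unrelated/related
boundary is 0.15, a ≈ 1% tail). Fewer than 50 informative loci sets a
low-confidence flag.

Relationship classes (π̂ thresholds, config-overridable): clone or
bud sport ≥ 0.9; parent–offspring [0.4, 0.6] with Z0 ≤ 0.05;
first-degree other (full sibs) [0.4, 0.6] with Z0 > 0.05; related
[0.15, 0.4); otherwise unrelated. Clone groups are connected
components of clone edges (transitive closure), singletons omitted.
Haplotype grouping labels identical ordered genotype strings over a
region H001, H002, … by descending frequency; any missing call leaves
a sample unassigned.

## F1 bin maps

Only pseudo-testcross markers (het in exactly one parent) enter the
origin recoding for that parent; het×het markers are phase-ambiguous
in het progeny and are used for segregation tests only. For a marker
with homozygous-parent genotype H, a progeny call c implies the het
parent transmitted allele c − H/2; Mendelian-inconsistent calls become
missing.

Because which parental *haplotype* carries the ref allele changes from
marker to marker, transmitted-allele codes are phased by walking each
chromosome in physical order and flipping any marker that disagrees
with the running per-progeny consensus in a majority of progeny. This
is reliable when fewer than half the progeny recombine between
adjacent informative markers — comfortably true at realistic marker
densities — and leaves one arbitrary global flip per chromosome, which
does not affect bins or crossover counts. Marker order is taken from
the physical map (no linkage-map ordering is performed), justified
when map/physical collinearity is strong.

Bins merge consecutive markers whose origin vectors are compatible
(equal wherever both are non-missing, against a consensus that fills
in as the bin extends); all-missing markers merge into the current
bin. On error-free simulations bins per chromosome equal distinct
observable breakpoint intervals + 1 and every interval is recovered
exactly — "observable" meaning crossovers mapped to marker intervals
with odd parity (two crossovers between the same two markers cancel
and are invisible to any marker-based method).

Crossovers are transitions between adjacent bins' origin calls per
progeny, placed in the interval between the flanking informative
markers. Single-bin blips flanked by equal calls (double recombinants
within a 3-bin span) are treated as genotyping errors and smoothed by
default (`smooth=False` keeps them).

Segregation tests are Pearson chi-square against 1:1 (testcross,
df = 1) or 1:2:1 (intercross, df = 2), requiring ≥ 20 called progeny.
Distortion regions are runs of ≥ 3 consecutive markers significant at
the Bonferroni-corrected level α/n_markers. The type-I rate at
α = 0.05 with 100 progeny is ≈ 0.053 (binomial discreteness, within
[0.035, 0.065]).

## Synthetic data

`simulate_genome` draws iid bases at a target GC and plants repeat
copies with exact mismatch counts (truth table returned) — the
adversarial input for the homology rules. `simulate_population` is a
Balding–Nichols island model: ancestral frequency p ~ U(maf_floor,
1−maf_floor), population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
Hardy–Weinberg genotypes within populations; F equals the expected
Weir–Cockerham F_ST, making recovery checks analytic. Chosen over a
coalescent simulator precisely for that closed form; the trade-off is
no linkage disequilibrium, no site-frequency-spectrum realism (so
Tajima's D on these cohorts is positive by construction — the neutral
D ≈ 0 check uses an msprime coalescent simulation instead), and no
missingness structure. `simulate_f1` draws per-gamete crossover counts
Poisson(cM/100) per chromosome with uniform positions and no
interference, then applies genotyping error (calls shifted to another
code) and missingness independently; every breakpoint is recorded.
All generators are bit-reproducible given (seed, config).

What passing tests therefore show: the estimators and constructions
are correct on data satisfying their own model assumptions. They do
not show robustness to LD, allele-frequency misspecification,
batch-variable missingness or reference bias in real capture data.

## Problem sizes and defaults

Simulated genomes in examples, tests and the acceptance script are
hundreds of kb with 10-kb selection windows — the same per-window
candidate densities as a real design at 1/10 linear scale, chosen so
the full stack (including the exhaustive homology verification) runs
in seconds. Estimator-recovery checks use the sizes their statistics
need: 2 × 50 samples and 2 000 SNPs for F_ST, 200 pairs per class at
384 loci for IBD, 500 progeny × 1 000 markers for bin-map exactness,
2 000 markers × 100 progeny for segregation calibration.

## Known limitations

* Homology rules are ungapped; no Tm/secondary-structure probe
  scoring.
* One locus per window is a fixed policy, not an optimization over
  panel composition.
* The QR parity row detects but cannot correct corruption.
* IBD assumes unlinked loci and cohort-estimated frequencies; close
  inbreeding or strong structure biases π̂.
* Bin maps require physical marker order and majority-phaseable
  chains; extremely sparse or clustered markers can break the phasing
  walk.
* No genetic-map distances (cM), marker ordering, or QTL scanning.
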