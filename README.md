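# panelsmith

Design and evaluate targeted liquid-chip SNP panels for highly
heterozygous crop genomes, and run the downstream analyses such panels
exist for: population-genetic characterization, germplasm
fingerprinting and kinship, and F1 recombination bin maps.

Deep resequencing of heterozygous perennials (fruit trees such as
litchi) is expensive, and hybridization arrays genotype heterozygous
sites poorly. A liquid chip — solution-phase capture probes targeting a
few tens of thousands of representative SNPs — is the practical middle
ground, but only if the loci are chosen well. `panelsmith` implements
the whole design-and-validation loop as a library with a thin CLI.

## What it computes

**Representative-SNP selection.** From a multi-sample VCF, a site is a
candidate when (all inequalities strict)

* missing rate < 0.1, minor allele frequency (MAF) > 0.35, observed
  heterozygosity H_obs < 0.5;
* both 110-bp flanking probe sequences have GC content in [0.3, 0.7]
  and together hit fewer than 5 homologous regions genome-wide, where a
  region is homologous if an ungapped alignment has more than 40 bp of
  identical sequence, more than 85% identity over 80 bp, or more than
  95% identity over 70 bp (both strands; exhaustive seeded scan
  validated against a brute-force oracle);
* at most one locus (the highest scoring) is kept per fixed genomic
  window (default 100 kb).

Under the MAF filter the chip-style PIC — expected heterozygosity
2p(1−p) — is confined to (0.455, 0.5], so every retained locus is near
maximally informative.

**Panel evaluation.** Per-site MAF/PIC spectra, adjacent-locus spacing,
SNP-count vs chromosome-length correlation; windowed nucleotide
diversity π = c_ref·c_alt / C(n,2) per site (per-bp in sliding
windows), Weir–Cockerham (1984) F_ST as a ratio of variance-component
sums, Tajima's D, and chip-vs-whole-genome concordance.

**Fingerprinting.** Distillation of a panel to k = 384 spaced loci,
lossless parity-checked QR-style genotype grids, PLINK-style
method-of-moments IBD (Z0, Z1, Z2, π̂ = Z2 + Z1/2), relationship
classification (clone/bud-sport ≥ 0.9; parent–offspring π̂ ∈ [0.4, 0.6]
with Z0 ≤ 0.05), clone groups as connected components, and regional
haplotype grouping.

**Genetic mapping.** Pseudo-testcross cross-type classification
(0/0×0/1, 0/1×0/1, 0/1×1/1), parental-origin phasing, recombination
bins (runs of markers with compatible progeny transmission vectors),
per-parent crossover maps, and chi-square segregation-distortion scans
(1:1 or 1:2:1, Bonferroni-corrected runs).

A seeded `synth_data` module simulates genomes with planted repeats,
Balding–Nichols structured populations (divergence F = expected F_ST),
and F1 crosses with recorded crossover breakpoints, so every estimator
is testable against known truth.

## Worked example

`examples/01_design_panel.py` designs a panel on a simulated 360-kb,
three-chromosome cohort (2 populations × 40 samples, 2 000 SNPs):

```text
QC: 378/2000 sites pass
probes: 378/378 pass GC + specificity
panel: 36 loci, mean adjacent spacing 9.7 kb
MAF range 0.456-0.500, PIC range 0.496-0.500
SNP-count vs chromosome-length Pearson r = 1.00
```

The QC stage keeps ~19% of sites (the MAF > 0.35 rule is the main
filter), the random genome contains almost no repetitive probe
failures, and one-locus-per-10-kb-window selection yields an evenly
spaced panel whose MAF/PIC ranges sit in the bands forced by the
filter. The other examples cover population statistics
(`02_popgen_stats.py`), fingerprinting and IBD kinship
(`03_fingerprint_ibd.py`) and F1 bin maps (`04_binmap_f1.py`); each
prints a few numbers and a line on how to read them. The CLI mirrors
the same steps (`panelsmith qc|probes|select|popgen|fingerprint|ibd|
binmap|simulate|run`).

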