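"""Seeded generators for genomes, structured populations and F1 crosses.

These generators provide inputs with known truth for every analysis in
the package:

* :func:`simulate_genome` — iid-base genomes at a target GC content with
  optionally planted near-identical repeats (to exercise the probe
  homology-specificity rules).
* :func:`simulate_population` — an island (Balding–Nichols) model:
  per-SNP ancestral frequency ``p ~ U(maf_floor, 1 - maf_floor)``,
  per-population frequency ``~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` and
  Hardy–Weinberg genotypes within populations.  The divergence
  parameter ``F`` is the expected Weir–Cockerham Fst, which makes
  estimator-recovery checks analytic.
* :func:`simulate_f1` — an outcrossing F1 design ('female' x 'male'):
  per-gamete crossover counts are Poisson(map length in Morgans) with
  uniform positions and no interference; every breakpoint is recorded.

All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, ReferenceGenome, SiteRecord

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PlantedRepeat:
    """A source interval copied ``n_copies`` times with mismatches.

    ``start``/``end`` are 0-based half-open on ``chrom``.
    """

    chrom: str
    start: int
    end: int
    n_copies: int
    mismatches: int = 0
    reverse_complement: bool = False


@dataclass
class GenomeConfig:
    n_chroms: int = 2
    lengths: tuple[int, ...] = (100_000, 100_000)
    gc: float = 0.45
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)


@dataclass
class PopulationConfig:
    n_pops: int = 2
    samples_per_pop: int = 50
    n_snps: int = 2000
    divergence_F: float = 0.1
    maf_floor: float = 0.05
    missing_rate: float = 0.0


@dataclass
class CrossConfig:
    n_progeny: int = 200
    n_markers: int = 1000
    map_length_cM_female: float = 100.0
    map_length_cM_male: float = 100.0
    genotyping_error: float = 0.0
    missing_rate: float = 0.0


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode()[::-1].translate(_COMP).decode()


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(
    cfg: GenomeConfig, seed: int | np.random.Generator = 0
) -> tuple[ReferenceGenome, pd.DataFrame]:
    """Simulate a genome of iid bases; plant configured repeats.

    Returns the genome and a truth table with one row per planted copy
    (columns: repeat_index, src_chrom, src_start, src_end, chrom,
    start, end, mismatches, strand; coordinates 0-based half-open).
    """
    rng = np.random.default_rng(seed)
    lengths = list(cfg.lengths)[: cfg.n_chroms]
    if len(lengths) != cfg.n_chroms:
        raise ValueError("lengths must provide one entry per chromosome")
    if any(l < 10_000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    pg = cfg.gc / 2.0
    pa = (1.0 - cfg.gc) / 2.0
    probs = np.array([pa, pg, pg, pa])  # A C G T
    seqs: dict[str, np.ndarray] = {}
    for i, L in enumerate(lengths):
        idx = rng.choice(4, size=L, p=probs)
        seqs[f"chr{i + 1}"] = _BASE_ARR[idx].copy()
    truth_rows = []
    for ri, rep in enumerate(cfg.planted_repeats):
        src = seqs[rep.chrom][rep.start : rep.end].copy()
        seg_len = rep.end - rep.start
        if seg_len <= 0:
            raise ValueError("empty repeat source interval")
        for _ in range(rep.n_copies):
            seg = src.copy()
            if rep.mismatches:
                mpos = rng.choice(seg_len, size=rep.mismatches, replace=False)
                for m in mpos:
                    cur = seg[m]
                    choices = _BASE_ARR[_BASE_ARR != cur]
                    seg[m] = rng.choice(choices)
            strand = "+"
            if rep.reverse_complement and rng.random() < 0.5:
                seg = np.frombuffer(
                    revcomp(seg.tobytes().decode()).encode(), dtype="S1"
                ).copy()
                strand = "-"
            # place without overlapping the source interval
            for _attempt in range(1000):
                tchrom = f"chr{1 + rng.integers(cfg.n_chroms)}"
                L = len(seqs[tchrom])
                if L < seg_len:
                    continue
                tstart = int(rng.integers(0, L - seg_len + 1))
                if tchrom == rep.chrom and not (
                    tstart + seg_len <= rep.start or tstart >= rep.end
                ):
                    continue
                break
            else:
                raise ValueError("could not place planted repeat (genome too small)")
            seqs[tchrom][tstart : tstart + seg_len] = seg
            truth_rows.append(
                {
                    "repeat_index": ri,
                    "src_chrom": rep.chrom,
                    "src_start": rep.start,
                    "src_end": rep.end,
                    "chrom": tchrom,
                    "start": tstart,
                    "end": tstart + seg_len,
                    "mismatches": rep.mismatches,
                    "strand": strand,
                }
            )
    genome = ReferenceGenome({c: a.tobytes().decode() for c, a in seqs.items()})
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "repeat_index", "src_chrom", "src_start", "src_end",
            "chrom", "start", "end", "mismatches", "strand",
        ],
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Population (Balding–Nichols island model)
# ---------------------------------------------------------------------------

def simulate_population(
    cfg: PopulationConfig,
    genome: ReferenceGenome,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, dict[str, str], dict]:
    """Simulate a structured population on ``genome``.

    Returns (genotypes, sample -> population map, truth dict with keys
    ``ancestral_freqs``, ``pop_freqs`` (n_pops x n_snps), ``F``).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    if cfg.n_snps > int(lens.sum()) // 10:
        raise ValueError("SNP density infeasible for this genome")
    # allocate SNPs to chromosomes proportionally, positions uniform, no collision
    alloc = np.floor(cfg.n_snps * lens / lens.sum()).astype(int)
    while alloc.sum() < cfg.n_snps:
        alloc[int(rng.integers(len(chroms)))] += 1
    sites: list[SiteRecord] = []
    for c, k in zip(chroms, alloc):
        L = genome.lengths[c]
        pos = rng.choice(np.arange(2, L), size=k, replace=False)
        pos.sort()
        seq = genome[c]
        for p in pos:
            ref = seq[p - 1]
            if ref not in "ACGT":
                ref = "A"
            alt = rng.choice([b for b in "ACGT" if b != ref])
            sites.append(SiteRecord(c, int(p), ref, str(alt)))
    n_snps = len(sites)
    F = cfg.divergence_F
    anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=n_snps)
    if F > 0:
        a = anc * (1.0 - F) / F
        b = (1.0 - anc) * (1.0 - F) / F
        pop_freqs = rng.beta(a[None, :], b[None, :], size=(cfg.n_pops, n_snps))
    else:
        pop_freqs = np.tile(anc, (cfg.n_pops, 1))
    samples: list[str] = []
    pops: dict[str, str] = {}
    blocks = []
    for k in range(cfg.n_pops):
        label = f"Pop{k + 1}"
        names = [f"{label}_s{i + 1}" for i in range(cfg.samples_per_pop)]
        samples.extend(names)
        pops.update({n: label for n in names})
        blocks.append(
            rng.binomial(2, pop_freqs[k][None, :], size=(cfg.samples_per_pop, n_snps))
        )
    calls = np.concatenate(blocks, axis=0).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    g = GenotypeMatrix(samples, sites, calls)
    truth = {"ancestral_freqs": anc, "pop_freqs": pop_freqs, "F": F}
    return g, pops, truth


# ---------------------------------------------------------------------------
# F1 cross
# ---------------------------------------------------------------------------

def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    marker_pos: np.ndarray,
    chrom_len: int,
    map_length_cM: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """One meiotic product over a single chromosome; returns (alleles, breakpoints)."""
    n_co = rng.poisson(map_length_cM / 100.0)
    bps = sorted(int(b) for b in rng.integers(1, chrom_len + 1, size=n_co))
    phase = int(rng.integers(2))
    # phase switches at each breakpoint
    switch = np.searchsorted(bps, marker_pos, side="left") % 2
    use_b = (switch + phase) % 2
    alleles = np.where(use_b == 0, hap_a, hap_b)
    return alleles, bps


def simulate_f1(
    cfg: CrossConfig,
    genome: ReferenceGenome,
    seed: int | np.random.Generator = 0,
    parent_haplotypes: dict[str, np.ndarray] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Simulate an F1 cross between two outbred parents.

    The returned matrix holds the two parents (samples ``P1`` = female,
    ``P2`` = male) followed by progeny ``F1_001``...  The truth dict
    contains phased parental haplotypes (``hap_P1``, ``hap_P2``: arrays
    ``(2, n_markers)``) and the breakpoint table has one row per
    crossover (parent, progeny, chrom, pos 1-based).

    Genotyping errors replace the true call with one of the other two
    codes at the configured rate; missingness is masked independently.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(cfg.n_markers * lens / lens.sum()).astype(int)
    while alloc.sum() < cfg.n_markers:
        alloc[int(rng.integers(len(chroms)))] += 1
    sites: list[SiteRecord] = []
    chrom_slices: dict[str, slice] = {}
    start = 0
    for c, k in zip(chroms, alloc):
        L = genome.lengths[c]
        pos = rng.choice(np.arange(2, L), size=int(k), replace=False)
        pos.sort()
        seq = genome[c]
        for p in pos:
            ref = seq[p - 1]
            if ref not in "ACGT":
                ref = "A"
            alt = rng.choice([b for b in "ACGT" if b != ref])
            sites.append(SiteRecord(c, int(p), ref, str(alt)))
        chrom_slices[c] = slice(start, start + int(k))
        start += int(k)
    M = len(sites)
    if parent_haplotypes is None:
        freq = rng.uniform(0.3, 0.7, size=M)
        parent_haplotypes = {
            "P1": (rng.random((2, M)) < freq).astype(np.int8),
            "P2": (rng.random((2, M)) < freq).astype(np.int8),
        }
    hap1 = parent_haplotypes["P1"]
    hap2 = parent_haplotypes["P2"]
    marker_pos = np.array([s.pos for s in sites], dtype=np.int64)

    progeny_names = [f"F1_{i + 1:03d}" for i in range(cfg.n_progeny)]
    calls = np.zeros((2 + cfg.n_progeny, M), dtype=np.int8)
    calls[0] = hap1.sum(axis=0)
    calls[1] = hap2.sum(axis=0)
    bp_rows = []
    for pi, pname in enumerate(progeny_names):
        geno = np.zeros(M, dtype=np.int8)
        for parent, haps, cm in (
            ("P1", hap1, cfg.map_length_cM_female),
            ("P2", hap2, cfg.map_length_cM_male),
        ):
            for c in chroms:
                sl = chrom_slices[c]
                alleles, bps = _gamete(
                    haps[0, sl], haps[1, sl], marker_pos[sl],
                    genome.lengths[c], cm, rng,
                )
                geno[sl] += alleles
                for b in bps:
                    bp_rows.append(
                        {"parent": parent, "progeny": pname, "chrom": c, "pos": b}
                    )
        calls[2 + pi] = geno
    true_calls = calls.copy()
    if cfg.genotyping_error > 0:
        err = rng.random(calls[2:].shape) < cfg.genotyping_error
        shift = rng.integers(1, 3, size=calls[2:].shape).astype(np.int8)
        calls[2:] = np.where(err, (calls[2:] + shift) % 3, calls[2:])
    if cfg.missing_rate > 0:
        miss = rng.random(calls[2:].shape) < cfg.missing_rate
        calls[2:][miss] = MISSING
    g = GenotypeMatrix(["P1", "P2"] + progeny_names, sites, calls)
    breakpoints = pd.DataFrame(bp_rows, columns=["parent", "progeny", "chrom", "pos"])
    truth = {
        "hap_P1": hap1,
        "hap_P2": hap2,
        "true_calls": true_calls,
        "marker_order": [s.key for s in sites],
    }
    return g, breakpoints, truth
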