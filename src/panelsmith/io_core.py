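"""Core data containers and file I/O.

Conventions used throughout the package:

* Coordinates are 1-based inclusive internally (the VCF convention);
  BED export converts to 0-based half-open.
* Diploid genotype calls are encoded per (sample, site) as
  ``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.  Phase is
  collapsed at ingest; a half-missing genotype (``./1``) is missing.
* Only biallelic SNPs are retained; multiallelic and indel records are
  skipped at ingest with a warning counter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteRecord:
    """A single biallelic SNP locus (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def name(self) -> str:
        return self.id if self.id else f"{self.chrom}_{self.pos}"


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of diploid genotype codes.

    ``calls`` has shape ``(n_samples, n_sites)`` with entries in
    ``{0, 1, 2, -1}``.  Sites are kept sorted by (chrom, pos).
    """

    samples: list[str]
    sites: list[SiteRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        keys = [s.key for s in self.sites]
        if sorted(keys) != keys:
            order = sorted(range(len(keys)), key=lambda i: keys[i])
            self.sites = [self.sites[i] for i in order]
            self.calls = self.calls[:, order]
            keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) among sites")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(list(names), list(self.sites), self.calls[idx])

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.arange(self.n_sites)[mask_or_index]
        return GenotypeMatrix(
            list(self.samples), [self.sites[i] for i in idx], self.calls[:, idx]
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Subset to sites with ``start <= pos <= end`` on ``chrom`` (1-based)."""
        mask = np.array(
            [s.chrom == chrom and start <= s.pos <= end for s in self.sites]
        )
        return self.subset_sites(mask)


@dataclass
class ReferenceGenome:
    """In-memory reference: chrom -> uppercase DNA string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        for c, s in self.sequences.items():
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {c} has non-ACGTN characters: {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass
class FlankPair:
    """Left/right flanking sequences of a site, with truncation flags."""

    left: str
    right: str
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def truncated(self) -> bool:
        return self.left_truncated or self.right_truncated


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    region_filter: Iterable[tuple[str, int, int]] | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records, indels and records with non-ACGT alleles are
    skipped (counted and logged).  Phased and unphased genotypes are
    treated identically; half-missing genotypes become missing.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    region_filter
        Optional list of ``(chrom, start, end)`` 1-based inclusive
        intervals; only sites inside one of them are kept.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        sites: list[SiteRecord] = []
        rows: list[np.ndarray] = []
        n_skipped = 0
        for rec in vf:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_skipped += 1
                continue
            if region_filter is not None and not any(
                rec.chrom == c and s <= rec.pos <= e for c, s, e in region_filter
            ):
                continue
            calls = np.full(len(samples), MISSING, dtype=np.int8)
            for i, name in enumerate(samples):
                gt = rec.samples[name].get("GT")
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    continue
                if not all(a in (0, 1) for a in gt):
                    continue  # allele index outside biallelic range
                calls[i] = gt[0] + gt[1]
            sites.append(SiteRecord(rec.chrom, rec.pos, ref, alt, rec.id))
            rows.append(calls)
    if n_skipped:
        logger.warning("%s: skipped %d multiallelic/indel records", path, n_skipped)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    # drop duplicate coordinates (keep first occurrence)
    seen: set[tuple[str, int]] = set()
    keep = []
    for i, s in enumerate(sites):
        if s.key in seen:
            logger.warning("duplicate site %s:%d dropped", s.chrom, s.pos)
            continue
        seen.add(s.key)
        keep.append(i)
    sites = [sites[i] for i in keep]
    calls = calls[:, keep]
    return GenotypeMatrix(samples, sites, calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    g: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal GT-only VCF 4.2 file (plain text)."""
    path = Path(path)
    chroms: list[str] = []
    for s in g.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelsmith\n")
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, s in enumerate(g.sites):
            gts = "\t".join(_GT_STR[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id or '.'}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into memory (uses pyfaidx; builds .fai if absent)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    return ReferenceGenome({name: str(fa[name][:]) for name in fa.keys()})


def write_fasta(ref: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_flank(ref: ReferenceGenome, site: SiteRecord, flank_len: int) -> FlankPair:
    """Return the left/right flanking sequences of ``site``.

    ``left`` covers reference positions ``[pos - flank_len, pos - 1]`` and
    ``right`` covers ``[pos + 1, pos + flank_len]`` (1-based inclusive),
    truncated at contig ends with the corresponding flag set.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if site.chrom not in ref:
        raise KeyError(f"contig {site.chrom} not in reference")
    seq = ref[site.chrom]
    if site.pos > len(seq):
        raise ValueError(
            f"site {site.chrom}:{site.pos} beyond contig end ({len(seq)} bp)"
        )
    left_start = max(site.pos - flank_len - 1, 0)
    left = seq[left_start : site.pos - 1]
    right = seq[site.pos : site.pos + flank_len]
    return FlankPair(
        left=left,
        right=right,
        left_truncated=len(left) < flank_len,
        right_truncated=len(right) < flank_len,
    )


# ---------------------------------------------------------------------------
# Panel output
# ---------------------------------------------------------------------------

def write_panel(panel, prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel as ``<prefix>.bed`` + ``<prefix>.tsv``.

    The BED uses 0-based half-open single-base intervals; the TSV carries
    locus id, alleles and per-site statistics.  Returns the two paths.
    """
    if len(panel.sites) == 0:
        raise ValueError("cannot write an empty panel")
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    with open(bed_path, "w") as fh:
        for s in panel.sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.name}\n")
    df = panel.to_frame()
    df.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a panel TSV written by :func:`write_panel`."""
    return pd.read_csv(path, sep="\t")
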