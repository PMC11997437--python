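"""Probe-level GC and genome-wide homology-specificity filters.

Each QC-passing SNP is evaluated through its two 110-bp flanking
sequences (the capture-probe footprint).  A flank fails if its GC
fraction leaves the inclusive [0.3, 0.7] band, or if the pair of flanks
together hits five or more homologous regions elsewhere in the genome.

A genomic region is "homologous" to a probe when an ungapped alignment
against the probe satisfies at least one of three rules (all strict):

* more than 40 bp of identical sequence (an exact run of >= 41 bp);
* more than 85% identity over an 80-bp window (>= 69/80 matches);
* more than 95% identity over a 70-bp window (>= 67/70 matches).

Both strands are searched.  The scan is exhaustive: for every ungapped
alignment offset of the probe (and its reverse complement) against the
genome, windowed match counts are computed with vectorized cumulative
sums, so no qualifying region can be missed by seeding heuristics.
Qualifying windows are merged into maximal regions (gaps <= 10 bp)
before counting, and the probe's own source locus is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io_core import FlankPair, ReferenceGenome, SiteRecord, fetch_flank
from .synth_data import revcomp

DEFAULT_FLANK_LEN = 110
DEFAULT_GC_BAND = (0.3, 0.7)
DEFAULT_MAX_HITS = 5
MERGE_GAP = 10


class HomologyRule(str, Enum):
    IDENTICAL_GT40 = "IDENTICAL_GT40"
    SIM85_OVER80 = "SIM85_OVER80"
    SIM95_OVER70 = "SIM95_OVER70"


#: (rule, window length, minimum matches) — strict '>' thresholds:
#: >40 identical bp => 41/41; >85% of 80 => >=69; >95% of 70 => >=67.
RULES: tuple[tuple[HomologyRule, int, int], ...] = (
    (HomologyRule.IDENTICAL_GT40, 41, 41),
    (HomologyRule.SIM85_OVER80, 80, 69),
    (HomologyRule.SIM95_OVER70, 70, 67),
)


@dataclass
class HomologyHit:
    """A merged homologous genomic region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    rule: HomologyRule
    identity: float


@dataclass
class ProbeReport:
    site: SiteRecord
    left_gc: float | None
    right_gc: float | None
    gc_pass: bool
    hits: list[HomologyHit]
    hit_count: int
    specificity_pass: bool
    overall_pass: bool
    truncated: bool = False


def gc_content(seq: str) -> float:
    """GC fraction of ``seq``; N bases count in the denominator only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def _seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


from numba import njit

#: seed length for candidate-diagonal enumeration.  A 6-mer seed is
#: complete for every rule: the loosest window (80 bp with up to 11
#: mismatches) still forces an exact run of ceil(69/12) = 6 bp, so any
#: qualifying alignment diagonal shares at least one exact 6-mer with
#: the probe.  Each candidate diagonal is then verified exhaustively.
SEED_K = 6


@njit(cache=True)
def _verify_diagonals(genome, probe, diagonals, cover, ident):  # pragma: no cover
    """Exhaustively evaluate the rule windows on each alignment diagonal.

    Marks genomic positions covered by a qualifying window in ``cover``
    (uint8) and tracks the best window identity per position in
    ``ident`` (float32).  Rule windows wider than the probe are skipped.
    """
    G = genome.size
    P = probe.size
    cs = np.zeros(P + 1, dtype=np.int32)
    for di in range(diagonals.size):
        d = diagonals[di]
        lo = 0 if d >= 0 else -d
        hi = P if d + P <= G else G - d
        L = hi - lo
        if L < 41:
            continue
        for j in range(L):
            cs[j + 1] = cs[j] + (1 if genome[d + lo + j] == probe[lo + j] else 0)
        tot = cs[L]
        if tot < 41:
            continue
        for r in range(3):
            if r == 0:
                w, mmin = 41, 41
            elif r == 1:
                w, mmin = 80, 69
            else:
                w, mmin = 70, 67
            if w > P or w > L or tot < mmin:
                continue
            for t in range(L - w + 1):
                matches = cs[t + w] - cs[t]
                if matches >= mmin:
                    gs = d + lo + t
                    idv = matches / w
                    for x in range(gs, gs + w):
                        cover[x] = 1
                        if ident[x] < idv:
                            ident[x] = idv


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_hashes(seq_u8: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 hashes of all k-mers and a validity mask (no N)."""
    codes = _CODE[seq_u8]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        h = h * 4 + np.maximum(c, 0)
        valid &= c >= 0
    return h, valid


class _GenomeSeedIndex:
    """Sorted k-mer hash index of one contig, built once and reused."""

    def __init__(self, seq_u8: np.ndarray, k: int = SEED_K):
        h, valid = _kmer_hashes(seq_u8, k)
        pos = np.nonzero(valid)[0]
        hv = h[pos]
        order = np.argsort(hv, kind="stable")
        self.hashes = hv[order]
        self.positions = pos[order].astype(np.int64)

    def candidate_diagonals(self, probe_u8: np.ndarray, k: int = SEED_K) -> np.ndarray:
        ph, pvalid = _kmer_hashes(probe_u8, k)
        diagonals: list[np.ndarray] = []
        for ppos in np.nonzero(pvalid)[0]:
            lo = np.searchsorted(self.hashes, ph[ppos], side="left")
            hi = np.searchsorted(self.hashes, ph[ppos], side="right")
            if hi > lo:
                diagonals.append(self.positions[lo:hi] - int(ppos))
        if not diagonals:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(diagonals))


def _seed_index(ref: ReferenceGenome, chrom: str) -> _GenomeSeedIndex:
    cache = getattr(ref, "_seed_index_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(ref, "_seed_index_cache", cache)
    if chrom not in cache:
        cache[chrom] = _GenomeSeedIndex(_seq_to_u8(ref[chrom]))
    return cache[chrom]


def _scan_strand(
    probe_u8: np.ndarray,
    genome_u8: np.ndarray,
    index: _GenomeSeedIndex,
    cover: np.ndarray,
    ident: np.ndarray,
) -> None:
    """Accumulate qualifying-window coverage of one probe orientation."""
    if len(genome_u8) == 0 or len(probe_u8) < 41:
        return
    diagonals = index.candidate_diagonals(probe_u8)
    if diagonals.size:
        _verify_diagonals(genome_u8, probe_u8, diagonals, cover, ident)


def _cover_to_windows(
    cover: np.ndarray, ident: np.ndarray
) -> list[tuple[int, int, float]]:
    """Contiguous covered runs as (start, end, max identity) intervals."""
    padded = np.zeros(len(cover) + 2, dtype=np.int8)
    padded[1:-1] = cover
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [
        (int(s), int(e), float(ident[s:e].max())) for s, e in zip(starts, ends)
    ]


def _merge_windows(
    windows: list[tuple[int, int, float]], gap: int = MERGE_GAP
) -> list[tuple[int, int, float]]:
    """Merge overlapping/nearby qualifying windows into maximal regions."""
    if not windows:
        return []
    windows = sorted(windows)
    merged = []
    cs, ce, ci = windows[0]
    for s, e, i in windows[1:]:
        if s <= ce + gap:
            ce = max(ce, e)
            ci = max(ci, i)
        else:
            merged.append((cs, ce, ci))
            cs, ce, ci = s, e, i
    merged.append((cs, ce, ci))
    return merged


def count_homologous_regions(
    probe: str,
    ref: ReferenceGenome,
    self_locus: tuple[str, int, int] | None = None,
    merge_gap: int = MERGE_GAP,
) -> list[HomologyHit]:
    """Find every homologous region of ``probe`` in the genome.

    ``self_locus`` is a (chrom, start, end) 1-based inclusive interval;
    regions overlapping it (the probe's own source) are excluded.
    Windows from different rules that overlap (within ``merge_gap`` bp)
    are merged into a single region, since the specificity criterion
    counts regions rather than alignments.
    """
    probe = probe.upper()
    if len(probe) < min(w for _, w, _ in RULES):
        raise ValueError(
            f"probe shorter than the smallest rule window "
            f"({min(w for _, w, _ in RULES)} bp)"
        )
    if len(probe) < max(w for _, w, _ in RULES):
        import logging

        logging.getLogger(__name__).warning(
            "probe length %d: rules with longer windows skipped", len(probe)
        )
    strands = (_seq_to_u8(probe), _seq_to_u8(revcomp(probe)))
    hits: list[HomologyHit] = []
    for chrom, seq in ref.sequences.items():
        g_u8 = _seq_to_u8(seq)
        index = _seed_index(ref, chrom)
        cover = np.zeros(len(g_u8), dtype=np.uint8)
        ident_arr = np.zeros(len(g_u8), dtype=np.float32)
        for p_u8 in strands:
            _scan_strand(p_u8, g_u8, index, cover, ident_arr)
        windows = _cover_to_windows(cover, ident_arr)
        for s0, e0, ident in _merge_windows(windows, merge_gap):
            start1, end1 = s0 + 1, e0  # to 1-based inclusive
            if self_locus is not None:
                sc, ss, se = self_locus
                if chrom == sc and not (end1 < ss or start1 > se):
                    continue
            rule = _classify_rule(ident)
            hits.append(HomologyHit(chrom, start1, end1, rule, ident))
    hits.sort(key=lambda h: (h.chrom, h.start))
    return hits


def _classify_rule(identity: float) -> HomologyRule:
    if identity >= 1.0:
        return HomologyRule.IDENTICAL_GT40
    if identity >= 67 / 70:
        return HomologyRule.SIM95_OVER70
    return HomologyRule.SIM85_OVER80


def evaluate_probe(
    site: SiteRecord,
    ref: ReferenceGenome,
    flank_len: int = DEFAULT_FLANK_LEN,
    gc_band: tuple[float, float] = DEFAULT_GC_BAND,
    max_hits: int = DEFAULT_MAX_HITS,
    mode: str = "flanks",
) -> ProbeReport:
    """Full probe evaluation of one site: GC band plus specificity.

    ``mode='flanks'`` (default) evaluates the left and right flank
    separately and requires both inside the GC band;
    ``mode='centered'`` evaluates a single window of ``flank_len`` bp
    centred on the SNP.  Truncated flanks at contig edges fail
    automatically.  ``specificity_pass`` requires strictly fewer than
    ``max_hits`` de-duplicated homologous regions over both flanks.
    """
    fl = fetch_flank(ref, site, flank_len)
    if mode == "centered":
        half = flank_len // 2
        left = fl.left[-half:] if fl.left else ""
        seqs = [left + site.ref + fl.right[: flank_len - len(left) - 1]]
        truncated = len(seqs[0]) < flank_len
        gcs = [gc_content(seqs[0])] if seqs[0] else [None]
        left_gc = right_gc = gcs[0]
    elif mode == "flanks":
        seqs = [fl.left, fl.right]
        truncated = fl.truncated
        left_gc = gc_content(fl.left) if fl.left else None
        right_gc = gc_content(fl.right) if fl.right else None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    lo, hi = gc_band
    gc_vals = [v for v in (left_gc, right_gc) if v is not None]
    gc_pass = (
        not truncated
        and len(gc_vals) > 0
        and all(lo <= v <= hi for v in gc_vals)
    )

    self_locus = (site.chrom, site.pos - flank_len, site.pos + flank_len)
    windows_by_chrom: dict[str, list[HomologyHit]] = {}
    all_hits: list[HomologyHit] = []
    if not truncated:
        raw: list[tuple[str, int, int, float]] = []
        for seq in seqs:
            if len(seq) >= min(w for _, w, _ in RULES):
                for h in count_homologous_regions(seq, ref, self_locus=self_locus):
                    raw.append((h.chrom, h.start, h.end, h.identity))
        # de-duplicate across the two flanks by re-merging per chromosome
        for chrom in sorted({r[0] for r in raw}):
            wins = [(s - 1, e, i) for c, s, e, i in raw if c == chrom]
            for s0, e0, ident in _merge_windows(wins):
                all_hits.append(
                    HomologyHit(chrom, s0 + 1, e0, _classify_rule(ident), ident)
                )
    hit_count = len(all_hits)
    specificity_pass = not truncated and hit_count < max_hits
    overall_pass = gc_pass and specificity_pass
    return ProbeReport(
        site=site,
        left_gc=left_gc,
        right_gc=right_gc,
        gc_pass=gc_pass,
        hits=all_hits,
        hit_count=hit_count,
        specificity_pass=specificity_pass,
        overall_pass=overall_pass,
        truncated=truncated,
    )


def evaluate_probes(
    sites: list[SiteRecord],
    ref: ReferenceGenome,
    flank_len: int = DEFAULT_FLANK_LEN,
    gc_band: tuple[float, float] = DEFAULT_GC_BAND,
    max_hits: int = DEFAULT_MAX_HITS,
    mode: str = "flanks",
) -> list[ProbeReport]:
    """Evaluate a list of candidate sites (see :func:`evaluate_probe`)."""
    return [
        evaluate_probe(s, ref, flank_len=flank_len, gc_band=gc_band,
                       max_hits=max_hits, mode=mode)
        for s in sites
    ]


def probe_report_frame(reports: list[ProbeReport]):
    """Tabular summary of probe reports (one row per site)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [r.site.chrom for r in reports],
            "pos": [r.site.pos for r in reports],
            "id": [r.site.name for r in reports],
            "left_gc": [r.left_gc for r in reports],
            "right_gc": [r.right_gc for r in reports],
            "gc_pass": [r.gc_pass for r in reports],
            "hit_count": [r.hit_count for r in reports],
            "specificity_pass": [r.specificity_pass for r in reports],
            "truncated": [r.truncated for r in reports],
            "overall_pass": [r.overall_pass for r in reports],
        }
    )
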