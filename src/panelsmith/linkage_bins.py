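"""F1 cross-type classification, recombination bin maps, per-parent
crossover maps and segregation-distortion scans.

The mapping design is a pseudo-testcross: markers heterozygous in one
parent and homozygous in the other reveal which of the het parent's two
alleles each progeny received, so runs of markers with identical
progeny transmission vectors collapse into recombination bins.  Marker
order is taken from the physical map.  Het x het (ABxAB) markers are
phase-ambiguous in het progeny and are used only for segregation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import MISSING, GenotypeMatrix


class CrossKind(str, Enum):
    AAxAB = "AAxAB"  # P1 homozygous, P2 heterozygous
    ABxAB = "ABxAB"  # both heterozygous
    ABxBB = "ABxBB"  # P1 heterozygous, P2 homozygous
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class CrossType:
    kind: CrossKind
    informative_parent: str | None  # 'P1', 'P2', 'both' or None
    flagged_missing: bool = False


@dataclass
class Bin:
    chrom: str
    start: int
    end: int
    marker_ids: list[str]
    pattern: np.ndarray  # per-progeny origin {0, 1, -1}


@dataclass
class RecombinationMap:
    parent: str
    crossovers: pd.DataFrame  # progeny, chrom, left_pos, right_pos
    per_progeny_counts: pd.Series
    interval_counts: pd.DataFrame

    @property
    def mean_crossovers(self) -> float:
        return float(self.per_progeny_counts.mean())


def classify_cross(gP1: int, gP2: int) -> CrossType:
    """Classify a marker by its parental genotype pair.

    Informative configurations (up to allele relabeling): one parent
    het with the other homozygous (AAxAB when P2 is the het parent,
    ABxBB when P1 is), and het x het (ABxAB).  Identical homozygotes
    and opposite homozygotes are uninformative; a missing parental call
    is uninformative and flagged.
    """
    if gP1 == MISSING or gP2 == MISSING:
        return CrossType(CrossKind.UNINFORMATIVE, None, flagged_missing=True)
    het1, het2 = gP1 == 1, gP2 == 1
    if het1 and het2:
        return CrossType(CrossKind.ABxAB, "both")
    if het2 and not het1:
        return CrossType(CrossKind.AAxAB, "P2")
    if het1 and not het2:
        return CrossType(CrossKind.ABxBB, "P1")
    return CrossType(CrossKind.UNINFORMATIVE, None)


def classify_crosses(g: GenotypeMatrix, p1: str, p2: str) -> list[CrossType]:
    i1, i2 = g.sample_index(p1), g.sample_index(p2)
    return [classify_cross(int(a), int(b)) for a, b in zip(g.calls[i1], g.calls[i2])]


# ---------------------------------------------------------------------------
# Parental-origin recoding (pseudo-testcross)
# ---------------------------------------------------------------------------

def origin_matrix(
    g: GenotypeMatrix, p1: str, p2: str, parent: str, phase: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Recode progeny genotypes to parental-origin calls for one parent.

    Uses only markers where ``parent`` is heterozygous and the other
    parent homozygous (pseudo-testcross markers).  For such a marker
    with homozygous-parent genotype ``H``, a progeny call ``c`` implies
    the het parent transmitted allele ``c - H/2``; Mendelian-
    inconsistent and missing calls become -1.

    Which of the het parent's two *haplotypes* carries the ref allele
    varies from marker to marker, so raw transmitted-allele codes are
    not comparable along a chromosome.  With ``phase=True`` (default)
    each marker is oriented against the running consensus of the
    preceding markers by majority agreement across progeny, yielding
    haplotype-origin codes {0 = haplotype a, 1 = haplotype b} that are
    consistent within a chromosome (up to one arbitrary global flip
    per chromosome).

    Returns (origin matrix of shape (n_markers_used, n_progeny),
    indices of the used markers in ``g``).
    """
    if parent not in ("P1", "P2"):
        raise ValueError("parent must be 'P1' or 'P2'")
    crosses = classify_crosses(g, p1, p2)
    want = CrossKind.ABxBB if parent == "P1" else CrossKind.AAxAB
    idx = np.array([i for i, c in enumerate(crosses) if c.kind == want], dtype=int)
    i1, i2 = g.sample_index(p1), g.sample_index(p2)
    prog_rows = [i for i in range(g.n_samples) if i not in (i1, i2)]
    hom_parent_row = i2 if parent == "P1" else i1
    out = np.full((len(idx), len(prog_rows)), -1, dtype=np.int8)
    for r, m in enumerate(idx):
        H = int(g.calls[hom_parent_row, m])
        prog = g.calls[prog_rows, m].astype(np.int16)
        origin = prog - H // 2
        origin[(prog == MISSING) | (origin < 0) | (origin > 1)] = -1
        out[r] = origin.astype(np.int8)
    if phase and len(idx):
        out = phase_origins(out, g.chroms[idx])
    return out, idx


def phase_origins(origin: np.ndarray, chroms: np.ndarray) -> np.ndarray:
    """Orient transmitted-allele codes into a consistent haplotype frame.

    Walks each chromosome in marker order keeping a running consensus;
    a marker whose vector disagrees with the consensus in more progeny
    than it agrees is flipped (0 <-> 1).  The consensus is the most
    recent non-missing call per progeny, so sporadic missingness does
    not break the chain.
    """
    out = origin.copy()
    M, N = out.shape
    consensus = np.full(N, -1, dtype=np.int8)
    prev_chrom = None
    for m in range(M):
        if chroms[m] != prev_chrom:
            consensus = np.full(N, -1, dtype=np.int8)
            prev_chrom = chroms[m]
        vec = out[m]
        both = (vec != -1) & (consensus != -1)
        agree = int((vec[both] == consensus[both]).sum())
        disagree = int(both.sum()) - agree
        if disagree > agree:
            flip = vec != -1
            out[m, flip] = 1 - out[m, flip]
            vec = out[m]
        upd = vec != -1
        consensus[upd] = vec[upd]
    return out


# ---------------------------------------------------------------------------
# Bin construction
# ---------------------------------------------------------------------------

def build_bins(
    origin: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    marker_ids: list[str] | None = None,
) -> list[Bin]:
    """Merge consecutive markers into recombination bins.

    Two origin vectors are compatible when they agree wherever both are
    non-missing; a marker joins the current bin if it is compatible
    with the bin's consensus pattern (missing entries are filled as the
    bin extends).  A new bin starts at the first conflicting marker.
    An all-missing marker is compatible with everything and merges into
    the current bin.
    """
    M, N = origin.shape
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(M)]
    bins: list[Bin] = []
    cur_pattern: np.ndarray | None = None
    cur_ids: list[str] = []
    cur_chrom = None
    cur_start = cur_end = 0

    def close():
        if cur_pattern is not None:
            bins.append(Bin(cur_chrom, int(cur_start), int(cur_end),
                            list(cur_ids), cur_pattern.copy()))

    for m in range(M):
        vec = origin[m]
        if cur_pattern is None or chroms[m] != cur_chrom:
            close()
            cur_pattern = vec.astype(np.int8).copy()
            cur_ids = [marker_ids[m]]
            cur_chrom = chroms[m]
            cur_start = cur_end = positions[m]
            continue
        both = (cur_pattern != -1) & (vec != -1)
        if np.array_equal(cur_pattern[both], vec[both]):
            fill = (cur_pattern == -1) & (vec != -1)
            cur_pattern[fill] = vec[fill]
            cur_ids.append(marker_ids[m])
            cur_end = positions[m]
        else:
            close()
            cur_pattern = vec.astype(np.int8).copy()
            cur_ids = [marker_ids[m]]
            cur_start = cur_end = positions[m]
    close()
    return bins


def bins_frame(bins: list[Bin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "n_markers": [len(b.marker_ids) for b in bins],
            "pattern_hash": [hash(b.pattern.tobytes()) & 0xFFFFFFFF for b in bins],
        }
    )


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

def _smooth_calls(calls: np.ndarray) -> np.ndarray:
    """Flip single-bin blips flanked by two equal calls (double
    recombinants within a 3-bin span are treated as genotyping errors)."""
    out = calls.copy()
    for i in range(1, len(out) - 1):
        if (
            out[i] != -1
            and out[i - 1] != -1
            and out[i - 1] == out[i + 1]
            and out[i] != out[i - 1]
        ):
            out[i] = out[i - 1]
    return out


def recombination_map(
    bins: list[Bin],
    progeny_names: list[str],
    parent: str,
    smooth: bool = True,
) -> RecombinationMap:
    """Per-progeny crossovers from transitions between adjacent bins.

    A crossover is placed in the interval between the last marker of
    the preceding bin and the first marker of the following bin (both
    with non-missing origin calls for that progeny).  With
    ``smooth=True`` (default) isolated single-bin double recombinants
    are treated as genotyping errors and removed before counting.
    """
    rows = []
    counts = dict.fromkeys(progeny_names, 0)
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, cbins in by_chrom.items():
        patt = np.array([b.pattern for b in cbins])  # (n_bins, n_progeny)
        for pj, name in enumerate(progeny_names):
            calls = patt[:, pj]
            if smooth and len(calls) >= 3:
                calls = _smooth_calls(calls)
            known = np.nonzero(calls != -1)[0]
            for a, b_idx in zip(known[:-1], known[1:]):
                if calls[a] != calls[b_idx]:
                    counts[name] += 1
                    rows.append(
                        {
                            "progeny": name,
                            "chrom": chrom,
                            "left_pos": int(cbins[a].end),
                            "right_pos": int(cbins[b_idx].start),
                        }
                    )
    co = pd.DataFrame(rows, columns=["progeny", "chrom", "left_pos", "right_pos"])
    interval_counts = (
        co.groupby(["chrom", "left_pos", "right_pos"]).size().reset_index(name="n")
        if len(co)
        else pd.DataFrame(columns=["chrom", "left_pos", "right_pos", "n"])
    )
    return RecombinationMap(
        parent=parent,
        crossovers=co,
        per_progeny_counts=pd.Series(counts),
        interval_counts=interval_counts,
    )


# ---------------------------------------------------------------------------
# Segregation distortion
# ---------------------------------------------------------------------------

def segregation_test(
    progeny_calls: np.ndarray, cross: CrossType, min_called: int = 20
) -> tuple[float, int, float]:
    """Pearson chi-square test of Mendelian segregation at one marker.

    Testcross markers (AAxAB / ABxBB) expect a 1:1 het:hom split
    (df = 1); ABxAB markers expect 1:2:1 over hom-ref:het:hom-alt
    (df = 2).  Returns (chi2, df, p).
    """
    calls = np.asarray(progeny_calls)
    calls = calls[calls != MISSING]
    n = len(calls)
    if n < min_called:
        raise ValueError(f"only {n} called progeny (< {min_called})")
    if cross.kind in (CrossKind.AAxAB, CrossKind.ABxBB):
        het = int((calls == 1).sum())
        hom = n - het
        obs = np.array([het, hom], dtype=float)
        exp = np.array([n / 2, n / 2])
        df = 1
    elif cross.kind == CrossKind.ABxAB:
        obs = np.array(
            [(calls == 0).sum(), (calls == 1).sum(), (calls == 2).sum()], dtype=float
        )
        exp = np.array([n / 4, n / 2, n / 4])
        df = 2
    else:
        raise ValueError("segregation test undefined for uninformative markers")
    if (exp == 0).any():
        raise ValueError("zero expected count")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(sstats.chi2.sf(chi2, df))
    return chi2, df, p


def distortion_scan(
    g: GenotypeMatrix, p1: str, p2: str, min_called: int = 20
) -> pd.DataFrame:
    """Segregation chi-square for every informative marker."""
    crosses = classify_crosses(g, p1, p2)
    i1, i2 = g.sample_index(p1), g.sample_index(p2)
    prog_rows = [i for i in range(g.n_samples) if i not in (i1, i2)]
    rows = []
    for m, cr in enumerate(crosses):
        if cr.kind == CrossKind.UNINFORMATIVE:
            continue
        calls = g.calls[prog_rows, m]
        if (calls != MISSING).sum() < min_called:
            continue
        chi2, df, p = segregation_test(calls, cr, min_called=min_called)
        s = g.sites[m]
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "id": s.name,
                "cross": cr.kind.value,
                "chi2": chi2,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "cross", "chi2", "df", "p"])


def distortion_regions(
    scan: pd.DataFrame, alpha: float = 0.05, min_run: int = 3
) -> pd.DataFrame:
    """Merge runs of consecutive significant markers into regions.

    Significance uses a Bonferroni-corrected threshold
    ``alpha / n_markers``; runs of at least ``min_run`` consecutive
    significant markers on a chromosome become one region spanning the
    flanking marker positions.
    """
    if len(scan) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_markers", "min_p"])
    thr = alpha / len(scan)
    regions = []
    for chrom, grp in scan.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        sig = (grp["p"] < thr).to_numpy()
        pos = grp["pos"].to_numpy()
        pvals = grp["p"].to_numpy()
        i = 0
        while i < len(sig):
            if sig[i]:
                j = i
                while j + 1 < len(sig) and sig[j + 1]:
                    j += 1
                if j - i + 1 >= min_run:
                    regions.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[i]),
                            "end": int(pos[j]),
                            "n_markers": j - i + 1,
                            "min_p": float(pvals[i : j + 1].min()),
                        }
                    )
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_markers", "min_p"])
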