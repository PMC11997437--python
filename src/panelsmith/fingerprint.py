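"""Compact fingerprint sets, QR-style genotype profiles, pairwise IBD
and relationship classification, and regional haplotype grouping.

The fingerprint set distils a large panel to ``k`` loci (default 384)
by greedy selection maximizing chip-PIC under a minimum-spacing
constraint, with per-chromosome quotas proportional to chromosome
length (largest-remainder rounding).

IBD uses the classic method-of-moments: observed identity-by-state
(IBS) counts over informative loci are combined with the expected
P(IBS | IBD) probabilities — functions of cohort allele frequencies
with small-sample correction factors — and solved for the IBD-state
probabilities (Z0, Z1, Z2); pi-hat = Z2 + Z1/2.  Pairwise pi-hat is
~1 for clones/bud sports, ~0.5 for parent–offspring and full sibs
(the latter with Z0 > 0), and ~0 for unrelated pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, SiteRecord
from .panel_select import Panel

QR_VERSION = "panelsmith-qr-1"
QR_COLS = 32

#: relationship thresholds (PLINK-style practice); all config-overridable
DEFAULT_THRESHOLDS = {
    "clone_pihat": 0.9,
    "po_low": 0.4,
    "po_high": 0.6,
    "po_max_z0": 0.05,
    "related_low": 0.15,
}


@dataclass
class FingerprintSet:
    loci: list[SiteRecord]
    selection_scores: np.ndarray
    min_gap: int

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class QRProfile:
    """2-D grid profile: 2-bit genotype codes + a column-parity row."""

    sample: str
    n_loci: int
    matrix: np.ndarray  # (rows, QR_COLS) of 0/1
    version: str = QR_VERSION

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "sample": self.sample,
                "n_loci": self.n_loci,
                "rows": ["".join(map(str, row)) for row in self.matrix.tolist()],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "QRProfile":
        d = json.loads(text)
        mat = np.array([[int(ch) for ch in row] for row in d["rows"]], dtype=np.uint8)
        return cls(d["sample"], d["n_loci"], mat, d["version"])

    def to_png(self, path, cell: int = 10) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(self.matrix.shape[1] * cell / 72, self.matrix.shape[0] * cell / 72)
        )
        ax.imshow(1 - self.matrix, cmap="gray", interpolation="nearest")
        ax.set_axis_off()
        fig.savefig(path, bbox_inches="tight", pad_inches=0.05)
        plt.close(fig)


class QRChecksumError(ValueError):
    """Raised when a decoded profile fails its parity check."""


@dataclass
class IBDEstimate:
    pair: tuple[str, str]
    z0: float
    z1: float
    z2: float
    pihat: float
    n_informative: int
    low_confidence: bool = False


@dataclass
class RelationshipCall:
    pair: tuple[str, str]
    klass: str
    pihat: float
    z: tuple[float, float, float]
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Fingerprint selection
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = total - base.sum()
    order = np.argsort(-rem)
    base[order[:short]] += 1
    return base


def select_fingerprint(
    panel: Panel,
    chrom_lengths: dict[str, int],
    k: int = 384,
    min_gap: int = 100_000,
) -> FingerprintSet:
    """Distil a panel to ``k`` fingerprint loci.

    Per-chromosome target counts are proportional to chromosome length
    (largest-remainder rounding); within a chromosome, loci are taken
    greedily by descending chip-PIC subject to a ``min_gap`` spacing
    constraint.  If the constraint makes a quota infeasible the
    shortfall is filled best-effort from other chromosomes (with a
    warning).
    """
    if len(panel) < k:
        raise ValueError(f"panel has {len(panel)} < k={k} loci")
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    quotas = dict(zip(chroms, _largest_remainder(lens, k)))
    df = panel.to_frame()
    df["_i"] = np.arange(len(df))
    chosen: list[int] = []
    leftovers: list[pd.DataFrame] = []
    for c in chroms:
        grp = df[df["chrom"] == c].sort_values("pic_chip", ascending=False)
        taken_pos: list[int] = []
        taken = []
        for _, row in grp.iterrows():
            if len(taken) >= quotas[c]:
                break
            p = int(row["pos"])
            if all(abs(p - q) >= min_gap for q in taken_pos):
                taken_pos.append(p)
                taken.append(int(row["_i"]))
        chosen.extend(taken)
        leftovers.append(grp[~grp["_i"].isin(taken)])
    if len(chosen) < k:
        import logging

        logging.getLogger(__name__).warning(
            "spacing constraint infeasible: %d/%d loci selected; filling best-effort",
            len(chosen), k,
        )
        pool = pd.concat(leftovers).sort_values("pic_chip", ascending=False)
        by_chrom_pos = {c: [df.iloc[i]["pos"] for i in chosen if df.iloc[i]["chrom"] == c]
                        for c in chroms}
        for _, row in pool.iterrows():
            if len(chosen) >= k:
                break
            c, p = row["chrom"], int(row["pos"])
            if all(abs(p - q) >= min_gap for q in by_chrom_pos.get(c, [])):
                chosen.append(int(row["_i"]))
                by_chrom_pos.setdefault(c, []).append(p)
    chosen.sort(key=lambda i: (panel.sites[i].chrom, panel.sites[i].pos))
    loci = [panel.sites[i] for i in chosen]
    scores = panel.stats["pic_chip"].to_numpy()[chosen]
    return FingerprintSet(loci, scores, min_gap)


# ---------------------------------------------------------------------------
# QR profiles
# ---------------------------------------------------------------------------

_CODE_TO_BITS = {0: (0, 0), 1: (0, 1), 2: (1, 0), MISSING: (1, 1)}
_BITS_TO_CODE = {v: k for k, v in _CODE_TO_BITS.items()}


def encode_qr(genotypes: np.ndarray, sample: str = "") -> QRProfile:
    """Encode a genotype-code vector as a parity-protected bit grid.

    Each locus becomes 2 bits (00 hom-ref, 01 het, 10 hom-alt,
    11 missing) laid out row-major over 32 columns; unused cells are
    zero-padded and a final column-parity (XOR) row is appended, which
    detects any single flipped cell.
    """
    genotypes = np.asarray(genotypes)
    k = len(genotypes)
    bits = np.zeros(2 * k, dtype=np.uint8)
    for i, gcode in enumerate(genotypes):
        b0, b1 = _CODE_TO_BITS[int(gcode)]
        bits[2 * i] = b0
        bits[2 * i + 1] = b1
    rows = int(np.ceil(2 * k / QR_COLS))
    payload = np.zeros(rows * QR_COLS, dtype=np.uint8)
    payload[: 2 * k] = bits
    grid = payload.reshape(rows, QR_COLS)
    parity = np.bitwise_xor.reduce(grid, axis=0)
    return QRProfile(sample, k, np.vstack([grid, parity[None, :]]))


def decode_qr(profile: QRProfile) -> np.ndarray:
    """Invert :func:`encode_qr`; raises :class:`QRChecksumError` on a
    parity failure (any single corrupted cell is detected)."""
    mat = profile.matrix
    grid, parity = mat[:-1], mat[-1]
    if not np.array_equal(np.bitwise_xor.reduce(grid, axis=0), parity):
        raise QRChecksumError(f"parity check failed for sample {profile.sample!r}")
    bits = grid.reshape(-1)[: 2 * profile.n_loci]
    out = np.empty(profile.n_loci, dtype=np.int8)
    for i in range(profile.n_loci):
        out[i] = _BITS_TO_CODE[(int(bits[2 * i]), int(bits[2 * i + 1]))]
    return out


# ---------------------------------------------------------------------------
# IBD (method of moments)
# ---------------------------------------------------------------------------

def _expected_ibs_given_ibd(p: np.ndarray, n_alleles: float) -> np.ndarray:
    """Summed E[P(IBS=i | IBD=j)] over loci with small-sample corrections.

    Returns a 3x3 array E[i, j] = sum over loci of P(IBS=i | IBD=j).
    ``n_alleles`` is the number of alleles (2N) behind the frequency
    estimates; the correction factors de-bias the powers of p.
    """
    q = 1.0 - p
    Na = float(n_alleles)
    X = Na * p
    Y = Na * q
    c = Na / np.array([Na - 1.0, Na - 2.0, Na - 3.0])
    E = np.zeros((3, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        E[0, 0] = np.sum(
            2 * p**2 * q**2 * ((X - 1) / X) * ((Y - 1) / Y) * c[0] * c[1] * c[2]
        )
        E[1, 0] = np.sum(
            4 * p**3 * q * ((X - 1) / X) * ((X - 2) / X) * c[0] * c[1] * c[2]
            + 4 * p * q**3 * ((Y - 1) / Y) * ((Y - 2) / Y) * c[0] * c[1] * c[2]
        )
        E[1, 1] = np.sum(
            2 * p**2 * q * ((X - 1) / X) * c[0] * c[1]
            + 2 * p * q**2 * ((Y - 1) / Y) * c[0] * c[1]
        )
        E[2, 0] = np.sum(
            p**4 * ((X - 1) / X) * ((X - 2) / X) * ((X - 3) / X) * c[0] * c[1] * c[2]
            + q**4 * ((Y - 1) / Y) * ((Y - 2) / Y) * ((Y - 3) / Y) * c[0] * c[1] * c[2]
            + 4 * p**2 * q**2 * ((X - 1) / X) * ((Y - 1) / Y) * c[0] * c[1] * c[2]
        )
        E[2, 1] = np.sum(
            p**3 * ((X - 1) / X) * ((X - 2) / X) * c[0] * c[1]
            + q**3 * ((Y - 1) / Y) * ((Y - 2) / Y) * c[0] * c[1]
            + p**2 * q * ((X - 1) / X) * c[0] * c[1]
            + p * q**2 * ((Y - 1) / Y) * c[0] * c[1]
        )
        E[2, 2] = float(len(p))
    return E


def ibd_mom(
    gA: np.ndarray,
    gB: np.ndarray,
    freqs: np.ndarray,
    n_alleles: float | None = None,
    pair: tuple[str, str] = ("A", "B"),
    min_maf: float = 0.01,
    min_informative: int = 50,
) -> IBDEstimate:
    """Method-of-moments IBD estimate for one pair of samples.

    ``freqs`` are cohort alt-allele frequencies per locus; loci missing
    in either sample or with MAF < ``min_maf`` are skipped.  Z
    estimates are bounded to [0, 1] and renormalized;
    pi-hat = Z2 + Z1/2.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    freqs = np.asarray(freqs, dtype=float)
    maf = np.minimum(freqs, 1 - freqs)
    keep = (gA != MISSING) & (gB != MISSING) & (maf >= min_maf)
    a, b, p = gA[keep], gB[keep], freqs[keep]
    n_inf = int(keep.sum())
    if n_alleles is None:
        n_alleles = 500.0  # effectively asymptotic corrections
    ibs = 2 - np.abs(a - b)
    obs = np.array([(ibs == 0).sum(), (ibs == 1).sum(), (ibs == 2).sum()], float)
    E = _expected_ibs_given_ibd(p, n_alleles)
    z0 = obs[0] / E[0, 0] if E[0, 0] > 0 else 0.0
    z1 = (obs[1] - z0 * E[1, 0]) / E[1, 1] if E[1, 1] > 0 else 0.0
    z2 = (obs[2] - z0 * E[2, 0] - z1 * E[2, 1]) / E[2, 2] if E[2, 2] > 0 else 0.0
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    s = z.sum()
    z = z / s if s > 0 else np.array([1.0, 0.0, 0.0])
    pihat = float(z[2] + z[1] / 2)
    return IBDEstimate(
        pair=pair,
        z0=float(z[0]),
        z1=float(z[1]),
        z2=float(z[2]),
        pihat=min(max(pihat, 0.0), 1.0),
        n_informative=n_inf,
        low_confidence=n_inf < min_informative,
    )


def pairwise_ibd(
    g: GenotypeMatrix,
    loci: list[SiteRecord] | None = None,
    min_maf: float = 0.01,
) -> list[IBDEstimate]:
    """All-pairs IBD over the matrix (optionally restricted to ``loci``),
    with allele frequencies estimated from the cohort itself."""
    if loci is not None:
        keys = {s.key for s in loci}
        g = g.subset_sites([i for i, s in enumerate(g.sites) if s.key in keys])
    from .variant_qc import allele_counts

    ref, alt = allele_counts(g)
    n = ref + alt
    freqs = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    n_alleles = float(2 * g.n_samples)
    out = []
    for i in range(g.n_samples):
        for j in range(i + 1, g.n_samples):
            out.append(
                ibd_mom(
                    g.calls[i], g.calls[j], freqs,
                    n_alleles=n_alleles,
                    pair=(g.samples[i], g.samples[j]),
                    min_maf=min_maf,
                )
            )
    return out


def ibd_frame(estimates: list[IBDEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample1": [e.pair[0] for e in estimates],
            "sample2": [e.pair[1] for e in estimates],
            "z0": [e.z0 for e in estimates],
            "z1": [e.z1 for e in estimates],
            "z2": [e.z2 for e in estimates],
            "pihat": [e.pihat for e in estimates],
            "n_informative": [e.n_informative for e in estimates],
        }
    )


# ---------------------------------------------------------------------------
# Relationship classes
# ---------------------------------------------------------------------------

def classify_relationship(
    est: IBDEstimate, thresholds: dict | None = None
) -> RelationshipCall:
    """Map an IBD estimate to a relationship class.

    clone_or_bud_sport: pihat >= 0.9; parent_offspring: pihat in
    [0.4, 0.6] with Z0 <= 0.05; first_degree_other (e.g. full sibs):
    pihat in [0.4, 0.6] with Z0 > 0.05; related: pihat in [0.15, 0.4);
    otherwise unrelated.
    """
    t = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    ph = est.pihat
    if ph >= t["clone_pihat"]:
        k = "clone_or_bud_sport"
    elif t["po_low"] <= ph <= t["po_high"]:
        k = "parent_offspring" if est.z0 <= t["po_max_z0"] else "first_degree_other"
    elif t["related_low"] <= ph < t["po_low"]:
        k = "related"
    else:
        k = "unrelated"
    return RelationshipCall(
        pair=est.pair,
        klass=k,
        pihat=ph,
        z=(est.z0, est.z1, est.z2),
        low_confidence=est.low_confidence,
    )


def clone_groups(calls: list[RelationshipCall]) -> list[set[str]]:
    """Synonym/bud-sport groups: connected components of the graph whose
    edges are clone_or_bud_sport calls; singletons omitted."""
    import networkx as nx

    G = nx.Graph()
    for c in calls:
        if c.klass == "clone_or_bud_sport":
            G.add_edge(*c.pair)
    return [set(comp) for comp in nx.connected_components(G) if len(comp) >= 2]


# ---------------------------------------------------------------------------
# Haplotype grouping
# ---------------------------------------------------------------------------

def haplotype_groups(
    g: GenotypeMatrix,
    region: tuple[str, int, int],
    pops: dict[str, str] | None = None,
) -> tuple[dict[str, str | None], pd.DataFrame]:
    """Group samples by their ordered genotype string over a region.

    Samples sharing an identical genotype-code string over the region's
    sites receive the same label; labels are ordered by descending group
    size (H001, H002, ...).  Samples with any missing call in the region
    are unassigned (label None).  Returns (sample -> label, frequency
    table overall and per population if ``pops`` given).
    """
    sub = g.region(*region)
    if sub.n_sites == 0:
        raise ValueError(f"no sites in region {region}")
    strings: dict[str, str | None] = {}
    for i, s in enumerate(g.samples):
        v = sub.calls[i]
        strings[s] = None if (v == MISSING).any() else "".join(map(str, v))
    counts: dict[str, int] = {}
    for v in strings.values():
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    label_of = {s: f"H{i + 1:03d}" for i, (s, _) in enumerate(ordered)}
    labels = {smp: (label_of[v] if v is not None else None) for smp, v in strings.items()}
    rows = []
    for hap_string, n in ordered:
        lab = label_of[hap_string]
        row = {"haplotype": lab, "genotype_string": hap_string, "n": n,
               "freq": n / max(sum(counts.values()), 1)}
        if pops:
            for plab in sorted(set(pops.values())):
                members = [s for s, l in labels.items() if l == lab and pops.get(s) == plab]
                denom = sum(
                    1 for s, l in labels.items() if l is not None and pops.get(s) == plab
                )
                row[f"freq_{plab}"] = len(members) / denom if denom else float("nan")
        rows.append(row)
    return labels, pd.DataFrame(rows)
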