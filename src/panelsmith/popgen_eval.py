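"""Population-genetic estimators: nucleotide diversity, Weir–Cockerham
Fst and Tajima's D, windowed and per-fragment.

All estimators work from unphased genotype codes; a diploid contributes
two alleles per called site and missing genotypes simply reduce the
allele count at that site.

* Per-site pi is the unbiased mean pairwise difference
  ``c_ref * c_alt / C(n, 2)``; windowed pi divides the sum over
  contained sites by the window length in bp (the per-bp convention of
  the standard sliding-window tools).
* Fst is the Weir & Cockerham (1984) variance-components estimator,
  combined across sites/windows as a ratio of sums
  ``sum(a) / sum(a + b + c)``.  Negative window estimates are reported
  as computed, not clipped.
* Tajima's D uses the standard a1, a2, b1, b2, c1, c2, e1, e2 constants
  with n taken conservatively as the minimum called allele count across
  the region's sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import MISSING, GenotypeMatrix
from .variant_qc import allele_counts

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000


def site_pi(g: GenotypeMatrix, site_index: int) -> float:
    """Per-site nucleotide diversity: ``c_ref * c_alt / C(n, 2)``."""
    ref, alt = allele_counts(g.subset_sites([site_index]))
    n = int(ref[0] + alt[0])
    if n < 2:
        raise ValueError("site_pi needs at least 2 called alleles")
    return float(ref[0] * alt[0] / (n * (n - 1) / 2))


def _sites_pi(g: GenotypeMatrix) -> np.ndarray:
    ref, alt = allele_counts(g)
    n = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, ref * alt / np.maximum(n * (n - 1) / 2, 1), 0.0)
    return pi


def _windows(chrom_len: int, window: int, step: int):
    start = 0
    while start < chrom_len:
        yield start, min(start + window, chrom_len)
        start += step


def windowed_pi(
    g: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Sliding-window per-bp pi (0-based half-open window coordinates).

    Windows with no SNPs report pi = 0.
    """
    pi = _sites_pi(g)
    pos = g.positions
    chroms = g.chroms
    rows = []
    for c, L in chrom_lengths.items():
        on_c = chroms == c
        cpos = pos[on_c]
        cpi = pi[on_c]
        for ws, we in _windows(L, window, step):
            inside = (cpos > ws) & (cpos <= we)  # 1-based pos in (ws, we]
            rows.append(
                {
                    "chrom": c,
                    "start": ws,
                    "end": we,
                    "n_snps": int(inside.sum()),
                    "pi": float(cpi[inside].sum() / (we - ws)),
                }
            )
    return pd.DataFrame(rows)


def fragment_pi(
    g: GenotypeMatrix, fragments: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Per-fragment pi over (chrom, start, end) 0-based half-open
    intervals (e.g. captured probe regions).  Empty fragments report 0.
    """
    pi = _sites_pi(g)
    pos = g.positions
    chroms = g.chroms
    rows = []
    for c, s, e in fragments:
        inside = (chroms == c) & (pos > s) & (pos <= e)
        rows.append(
            {
                "chrom": c,
                "start": s,
                "end": e,
                "n_snps": int(inside.sum()),
                "pi": float(pi[inside].sum() / max(e - s, 1)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(
    g: GenotypeMatrix, pops: dict[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components a, b, c.

    Returns (a, b, c, usable) arrays over sites; ``usable`` marks sites
    where every population has at least one called genotype.
    """
    labels = sorted(set(pops.values()))
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    calls = g.calls
    n_i = []  # called genotype counts per pop per site
    p_i = []  # alt allele freq per pop per site
    h_i = []  # observed het fraction per pop per site
    for lab in labels:
        idx = [i for i, s in enumerate(g.samples) if pops.get(s) == lab]
        sub = calls[idx]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i, dtype=float)  # (r, S)
    p_i = np.array(p_i, dtype=float)
    h_i = np.array(h_i, dtype=float)
    r = len(labels)
    usable = (n_i >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nsum = n_i.sum(axis=0)
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    # monomorphic-across-all sites contribute nothing
    mono = np.isclose(pbar, 0) | np.isclose(pbar, 1)
    for arr in (a, b, c):
        arr[mono] = 0.0
    usable &= ~np.isnan(a) & ~np.isnan(b) & ~np.isnan(c)
    return a, b, c, usable


def fst_wc_global(g: GenotypeMatrix, pops: dict[str, str]) -> float:
    """Genome-wide weighted (ratio-of-sums) Weir–Cockerham Fst."""
    a, b, c, usable = _wc_components(g, pops)
    num = a[usable].sum()
    den = (a + b + c)[usable].sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def fst_wc(
    g: GenotypeMatrix,
    pops: dict[str, str],
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> tuple[pd.DataFrame, float]:
    """Windowed + genome-wide Weir–Cockerham Fst (ratio of sums).

    Windows where no site is usable (e.g. one population entirely
    missing) are flagged with NaN Fst.
    """
    a, b, c, usable = _wc_components(g, pops)
    pos = g.positions
    chroms = g.chroms
    rows = []
    for ch, L in chrom_lengths.items():
        on_c = chroms == ch
        cpos = pos[on_c]
        ca, cb, cc, cu = a[on_c], b[on_c], c[on_c], usable[on_c]
        for ws, we in _windows(L, window, step):
            inside = (cpos > ws) & (cpos <= we) & cu
            num = ca[inside].sum()
            den = (ca + cb + cc)[inside].sum()
            rows.append(
                {
                    "chrom": ch,
                    "start": ws,
                    "end": we,
                    "n_snps": int(inside.sum()),
                    "fst": float(num / den) if den != 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows), fst_wc_global(g, pops)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for n sequences."""
    if n < 3:
        raise ValueError("Tajima's D requires n >= 3 sequences")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    g: GenotypeMatrix, region: tuple[str, int, int] | None = None
) -> float:
    """Tajima's D over a region (chrom, start, end 1-based inclusive)
    or the whole matrix.

    theta_pi is the sum of per-site pairwise diversities; theta_W is
    S / a1.  n is the minimum called allele count across segregating
    sites (conservative under missingness).  Returns NaN when S = 0.
    """
    sub = g if region is None else g.region(*region)
    ref, alt = allele_counts(sub)
    seg = (ref > 0) & (alt > 0)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n = int((ref + alt)[seg].min())
    if n < 3:
        raise ValueError("Tajima's D requires >= 3 called alleles")
    k = tajima_constants(n)
    nn = (ref + alt)[seg].astype(float)
    theta_pi = float((ref[seg] * alt[seg] / (nn * (nn - 1) / 2)).sum())
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((theta_pi - theta_w) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance(
    full_windows: pd.DataFrame,
    chip_windows: pd.DataFrame,
    stat: str = "pi",
    min_snps: int = 1,
) -> tuple[float, int]:
    """Pearson r of a windowed statistic between two analyses.

    Windows are matched on (chrom, start, end); windows with fewer than
    ``min_snps`` SNPs in either analysis are excluded (empty windows
    carry no signal).  Returns (r, number of compared windows).
    """
    m = full_windows.merge(
        chip_windows, on=["chrom", "start", "end"], suffixes=("_full", "_chip")
    )
    m = m[(m["n_snps_full"] >= min_snps) & (m["n_snps_chip"] >= min_snps)]
    m = m.dropna(subset=[f"{stat}_full", f"{stat}_chip"])
    if len(m) < 3:
        raise ValueError("fewer than 3 shared windows")
    r, _ = sstats.pearsonr(m[f"{stat}_full"], m[f"{stat}_chip"])
    return float(r), int(len(m))
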