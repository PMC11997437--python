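"""Independent brute-force oracles used to validate the package's
optimized implementations.  These deliberately use naive algorithms
and separate formula transcriptions."""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")

# (window, min matches): >40 identical; >85% of 80; >95% of 70
RULE_WINDOWS = ((41, 41), (80, 69), (70, 67))


def brute_force_homology_positions(probe: str, genome: dict[str, str]):
    """Every genomic window qualifying under any homology rule, found by
    sliding every rule window over every contig and comparing against
    every probe substring (both probe orientations).

    Returns {chrom: sorted list of (start0, end0)} half-open intervals.
    """
    probes = [probe.upper(), probe.upper().translate(COMP)[::-1]]
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        g = np.frombuffer(seq.encode(), dtype=np.uint8)
        found: set[tuple[int, int]] = set()
        for w, mmin in RULE_WINDOWS:
            if w > len(probe):
                continue
            pw_list = []
            for p in probes:
                pu = np.frombuffer(p.encode(), dtype=np.uint8)
                if len(pu) >= w:
                    pw_list.append(np.lib.stride_tricks.sliding_window_view(pu, w))
            if not pw_list:
                continue
            pws = np.concatenate(pw_list, axis=0)  # (n_probe_windows, w)
            for gstart in range(0, len(g) - w + 1):
                gwin = g[gstart : gstart + w]
                matches = (pws == gwin[None, :]).sum(axis=1)
                if (matches >= mmin).any():
                    found.add((gstart, gstart + w))
        out[chrom] = sorted(found)
    return out


def merge_intervals(intervals, gap=10):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def brute_force_site_pi(alleles: list[int]) -> float:
    """Mean pairwise difference over all allele pairs, by enumeration."""
    n = len(alleles)
    diffs = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if alleles[i] != alleles[j]
    )
    return diffs / (n * (n - 1) / 2)


def wc_fst_oracle(pop_genotypes: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for ONE biallelic
    site, transcribed independently with explicit scalar arithmetic.

    ``pop_genotypes`` is a list of per-population genotype-code arrays
    (0/1/2, missing removed).  Returns (a, b, c).
    """
    r = len(pop_genotypes)
    n = [len(gp) for gp in pop_genotypes]
    p = [np.sum(gp) / (2 * len(gp)) for gp in pop_genotypes]
    h = [np.mean(gp == 1) for gp in pop_genotypes]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def tajimas_d_oracle(n: int, S: int, theta_pi: float) -> float:
    """Tajima's D from its closed-form constants, transcribed
    independently (harmonic sums written out explicitly)."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (theta_pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
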