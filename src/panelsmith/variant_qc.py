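"""Per-site statistics and the candidate-SNP inclusion filter.

The inclusion filter keeps highly informative, well-genotyped loci:
missing rate < 0.1, minor allele frequency > 0.35 and observed
heterozygosity < 0.5 (all inequalities strict).

Two flavours of polymorphic information content are reported.  The
classical biallelic PIC, ``1 - p^2 - q^2 - 2 p^2 q^2``, is bounded by
0.375.  The "chip PIC" used for scoring is the expected heterozygosity
``2pq`` (bounded by 0.5), which is the quantity whose attainable range
under the MAF > 0.35 filter is (0.455, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix

DEFAULT_MAX_MISSING = 0.1
DEFAULT_MIN_MAF = 0.35
DEFAULT_MAX_HOBS = 0.5


@dataclass
class SiteStats:
    call_rate: float
    maf: float
    hobs: float
    he: float
    pic_chip: float
    pic_classic: float
    n_called: int
    p_alt: float
    defined: bool = True


def allele_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) allele counts; het contributes one of each.

    Missing genotypes are excluded (no imputation).
    """
    calls = g.calls
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=0)
    ref = 2 * called.sum(axis=0) - alt
    return ref.astype(np.int64), alt.astype(np.int64)


def sites_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Vectorized per-site statistics for every site in ``g``.

    Returns a DataFrame indexed like ``g.sites`` with columns
    call_rate, maf, hobs, he, pic_chip, pic_classic, n_called, p_alt,
    defined.  Sites with no called genotype are flagged
    ``defined=False`` with NaN statistics.
    """
    calls = g.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_samples = g.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        call_rate = n_called / n_samples
        alt = np.where(called, calls, 0).sum(axis=0)
        p = alt / np.maximum(2 * n_called, 1)
        p = np.where(n_called > 0, p, np.nan)
        q = 1.0 - p
        maf = np.minimum(p, q)
        hobs = (calls == 1).sum(axis=0) / np.maximum(n_called, 1)
        hobs = np.where(n_called > 0, hobs, np.nan)
        he = 2.0 * p * q
        pic_classic = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
    df = pd.DataFrame(
        {
            "call_rate": call_rate,
            "maf": maf,
            "hobs": hobs,
            "he": he,
            "pic_chip": he,
            "pic_classic": pic_classic,
            "n_called": n_called,
            "p_alt": p,
            "defined": n_called > 0,
        }
    )
    return df


def site_stats(g: GenotypeMatrix, site_index: int) -> SiteStats:
    """Statistics for a single site (see :func:`sites_stats`)."""
    row = sites_stats(g.subset_sites([site_index])).iloc[0]
    return SiteStats(
        call_rate=float(row.call_rate),
        maf=float(row.maf),
        hobs=float(row.hobs),
        he=float(row.he),
        pic_chip=float(row.pic_chip),
        pic_classic=float(row.pic_classic),
        n_called=int(row.n_called),
        p_alt=float(row.p_alt),
        defined=bool(row.defined),
    )


def qc_filter(
    stats: pd.DataFrame,
    max_missing: float = DEFAULT_MAX_MISSING,
    min_maf: float = DEFAULT_MIN_MAF,
    max_hobs: float = DEFAULT_MAX_HOBS,
) -> np.ndarray:
    """Boolean inclusion mask per site.

    A site passes iff missing rate < ``max_missing`` AND
    maf > ``min_maf`` AND observed heterozygosity < ``max_hobs``
    (all strict).  Undefined sites never pass.
    """
    for name, t in (("max_missing", max_missing), ("min_maf", min_maf), ("max_hobs", max_hobs)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    # missing rate < max_missing, written on the call-rate side to avoid
    # float cancellation at the boundary (1 - 0.9 < 0.1 is true in binary)
    mask = (
        stats["defined"].to_numpy()
        & (stats["call_rate"].to_numpy() > 1.0 - max_missing)
        & (stats["maf"].to_numpy() > min_maf)
        & (stats["hobs"].to_numpy() < max_hobs)
    )
    return mask
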