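"""Uniform-spacing panel selection and panel characterization metrics.

Selection partitions each chromosome into fixed non-overlapping windows
(default 100 kb, anchored at position 0) and keeps at most one
candidate per window — the one with the highest chip-PIC (expected
heterozygosity), with deterministic tie-breaking by proximity to the
window centre, then by lowest position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import SiteRecord

DEFAULT_WINDOW = 100_000


@dataclass
class Panel:
    """Ordered selected loci with their per-site statistics."""

    sites: list[SiteRecord]
    stats: pd.DataFrame  # one row per site: maf, pic_chip, pic_classic, hobs, he
    window_size: int
    selection_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "id": [s.name for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
            }
        )
        return pd.concat([df, self.stats.reset_index(drop=True)], axis=1)


@dataclass
class PanelMetrics:
    n_sites: int
    mean_adjacent_distance: float
    frac_distance_le: dict[int, float]
    per_chrom_counts: dict[str, int]
    count_length_r: float
    count_length_p: float
    frac_maf_gt: dict[float, float]
    frac_pic_gt: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "mean_adjacent_distance": self.mean_adjacent_distance,
            "frac_distance_le": {str(k): v for k, v in self.frac_distance_le.items()},
            "per_chrom_counts": self.per_chrom_counts,
            "count_length_r": self.count_length_r,
            "count_length_p": self.count_length_p,
            "frac_maf_gt": {str(k): v for k, v in self.frac_maf_gt.items()},
            "frac_pic_gt": {str(k): v for k, v in self.frac_pic_gt.items()},
        }


def select_uniform(
    sites: list[SiteRecord],
    stats: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> Panel:
    """Pick at most one site per non-overlapping genomic window.

    ``sites`` are the probe-passing candidates; ``stats`` must carry one
    row per candidate (aligned by position) with at least ``pic_chip``
    and ``maf`` columns.  Within each window ``[k*window, (k+1)*window)``
    (0-based) the highest-``pic_chip`` candidate wins; ties break toward
    the window centre, then the lowest position.  Deterministic.
    """
    if len(sites) != len(stats):
        raise ValueError("sites and stats must align")
    if len(sites) == 0:
        import logging

        logging.getLogger(__name__).warning("empty candidate list: empty panel")
        return Panel([], stats.iloc[0:0], window)
    df = stats.reset_index(drop=True).copy()
    df["chrom"] = [s.chrom for s in sites]
    df["pos"] = [s.pos for s in sites]
    df["_i"] = np.arange(len(sites))
    df["win"] = (df["pos"].to_numpy() - 1) // window  # pos is 1-based
    centre = (df["win"] + 0.5) * window + 0.5
    df["_dist_centre"] = np.abs(df["pos"] - centre)
    chosen_idx: list[int] = []
    log_rows = []
    for (chrom, win), grp in df.groupby(["chrom", "win"], sort=True):
        grp = grp.sort_values(
            ["pic_chip", "_dist_centre", "pos"], ascending=[False, True, True]
        )
        best = int(grp.iloc[0]["_i"])
        chosen_idx.append(best)
        log_rows.append(
            {
                "chrom": chrom,
                "window_start": int(win * window),
                "n_candidates": len(grp),
                "chosen_pos": int(grp.iloc[0]["pos"]),
            }
        )
    chosen_idx.sort(key=lambda i: (sites[i].chrom, sites[i].pos))
    panel_sites = [sites[i] for i in chosen_idx]
    panel_stats = stats.reset_index(drop=True).iloc[chosen_idx].reset_index(drop=True)
    return Panel(panel_sites, panel_stats, window, pd.DataFrame(log_rows))


def panel_metrics(
    panel: Panel,
    chrom_lengths: dict[str, int],
    distance_thresholds: tuple[int, ...] = (10_000, 20_000),
    maf_thresholds: tuple[float, ...] = (0.45,),
    pic_thresholds: tuple[float, ...] = (0.45, 0.49),
) -> PanelMetrics:
    """Characterize a panel: spacing spectrum, per-chromosome density,
    SNP-count-vs-chromosome-length Pearson correlation, and MAF/PIC
    exceedance fractions.

    Adjacent distances are computed within chromosomes only.  The
    distance fractions use closed upper bounds (<= threshold).  With a
    single chromosome the correlation is undefined (NaN).
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    chroms = panel.chroms
    pos = panel.positions
    dists = []
    counts: dict[str, int] = {}
    for c in dict.fromkeys(chroms):
        p = pos[chroms == c]
        counts[c] = len(p)
        if len(p) > 1:
            dists.extend(np.diff(np.sort(p)).tolist())
    dists = np.array(dists, dtype=float)
    mean_d = float(dists.mean()) if len(dists) else float("nan")
    frac_le = {
        t: float((dists <= t).mean()) if len(dists) else float("nan")
        for t in distance_thresholds
    }
    xs = np.array([counts.get(c, 0) for c in chrom_lengths], dtype=float)
    ys = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
        r, p_val = sstats.pearsonr(xs, ys)
    elif len(xs) == 2 and np.std(xs) > 0 and np.std(ys) > 0:
        r = float(np.corrcoef(xs, ys)[0, 1])
        p_val = float("nan")
    else:
        r, p_val = float("nan"), float("nan")
    maf = panel.stats["maf"].to_numpy(dtype=float)
    pic = panel.stats["pic_chip"].to_numpy(dtype=float)
    return PanelMetrics(
        n_sites=len(panel),
        mean_adjacent_distance=mean_d,
        frac_distance_le=frac_le,
        per_chrom_counts=counts,
        count_length_r=float(r),
        count_length_p=float(p_val),
        frac_maf_gt={t: float((maf > t).mean()) for t in maf_thresholds},
        frac_pic_gt={t: float((pic > t).mean()) for t in pic_thresholds},
    )
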