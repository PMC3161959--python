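"""Poisson sliding-window scan for clusters of deleterious SNPs.

1-Mb windows stepped by 0.5 Mb are scanned across the genome.  Under the
null that deleterious SNPs accumulate at a constant genome-wide rate per kb
of accessible coding sequence, the count in a window is Poisson with mean
lambda = rate * accessible-CDS kb.  Windows with at least two deleterious
SNPs are ranked by the upper-tail probability P(X >= k); the most
significant 2% are selected (ties at the boundary included), and selected
windows that overlap or share a boundary are merged, keeping the
coordinates of the union and the smallest p of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WINDOW = 1_000_000
STEP = 500_000
MIN_DEL = 2
TOP_FRACTION = 0.02


@dataclass
class ScanResult:
    windows: pd.DataFrame  # all scanned windows with k, lambda, p, flags
    regions: pd.DataFrame  # merged selected regions (chrom, start, end, p)
    rate_per_kb: float  # genome-wide deleterious SNPs per accessible-CDS kb


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _mask_in_window(mask_s: np.ndarray, mask_e: np.ndarray,
                    start: int, end: int) -> int:
    o = np.minimum(mask_e, end) - np.maximum(mask_s, start)
    return int(o[o > 0].sum())


def merge_selected(selected: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent selected windows, keeping the chain's
    minimum p; coordinates extend to the union.  Idempotent and independent
    of input row order."""
    if selected.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "p"])
    rows = []
    for chrom, grp in selected.groupby("chrom"):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for w in grp.itertuples():
            if cur is not None and w.start <= cur["end"]:
                cur["end"] = max(cur["end"], w.end)
                cur["p"] = min(cur["p"], w.p)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(w.start),
                       "end": int(w.end), "p": float(w.p)}
        rows.append(cur)
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def scan(del_snps: pd.DataFrame, mask: pd.DataFrame,
         window: int = WINDOW, step: int = STEP,
         top_fraction: float = TOP_FRACTION,
         min_del: int = MIN_DEL) -> ScanResult:
    """Scan for windows with an excess of deleterious SNPs.

    ``del_snps``: chrom/pos of deleterious SNPs; ``mask``: chrom/start/end
    accessible-CDS intervals.  The genome-wide rate is computed from these
    inputs, never supplied.
    """
    if mask.empty or (mask["end"] - mask["start"]).sum() <= 0:
        raise ValueError("accessible-CDS mask is empty")
    total_kb = float((mask["end"] - mask["start"]).sum()) / 1000.0
    rate = len(del_snps) / total_kb

    rows = []
    for chrom, cmask in mask.groupby("chrom"):
        ms = cmask["start"].to_numpy()
        me = cmask["end"].to_numpy()
        pos = del_snps.loc[del_snps["chrom"] == chrom, "pos"].to_numpy()
        pos.sort()
        chrom_len = int(me.max())
        for start in range(0, chrom_len, step):
            end = start + window
            cds_bp = _mask_in_window(ms, me, start, end)
            k = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            lam = rate * cds_bp / 1000.0
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "cds_bp": cds_bp, "k": k, "lam": lam,
                "p": poisson_upper_tail(k, lam),
                "eligible": k >= min_del,
            })
    windows = pd.DataFrame(rows)

    eligible = windows[windows["eligible"]]
    windows["selected"] = False
    if len(eligible):
        n_sel = max(int(np.floor(top_fraction * len(eligible))), 1)
        thresh = np.sort(eligible["p"].to_numpy())[n_sel - 1]
        windows.loc[windows["eligible"] & (windows["p"] <= thresh),
                    "selected"] = True
    regions = merge_selected(windows[windows["selected"]])
    return ScanResult(windows=windows, regions=regions, rate_per_kb=rate)
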