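"""Hitchhiking vs non-hitchhiking contrasts of deleterious and neutral SNPs.

Sweep (hitchhiking) regions are labeled genomic intervals, typically the
overlap of multiple genome scans for selection.  SNP densities are measured
per kb of accessible aligned coding sequence inside and outside the
regions; the key summary is the fold change of the deleterious/neutral
ratio, with a one-sided Fisher exact test (enrichment of deleterious inside
regions), a two-proportion z-test on densities, and a log-ratio normal
confidence interval on the fold.

Also here: allele-frequency class breakdowns, empirical-outlier selection
of 100-kb iHS windows, distance-to-region binning that feeds the distance
regression, and disease-allele overlap ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ROUND_UNIT = 10_000
IHS_WINDOW = 100_000
IHS_ABS_CUTOFF = 2.0
IHS_BIN_INCREMENT = 25
IHS_MIN_SNPS = 10
IHS_MIN_WINDOWS = 100
IHS_MIN_WINDOWS_STRICT = 400  # applies at the 0.25% cutoff
DISEASE_COMMON_CUTOFF = 0.05
DISTANCE_BIN = 200_000

#: Allele-frequency classes: right-closed, left-open intervals of (0, 1].
FREQ_CLASSES = {
    "rare": (0.0, 0.008),
    "intermediate": (0.008, 0.059),
    "common": (0.059, 1.0),
}


def round_10kb(start: int, end: int, unit: int = ROUND_UNIT) -> tuple[int, int]:
    """Containment-preserving rounding to the 10-kb grid.

    Start is rounded down, end up, so the rounded interval always contains
    the original one (nearest-rounding could drop SNPs near the edges).
    """
    return (start // unit) * unit, -(-end // unit) * unit


@dataclass
class RegionSet:
    """Sorted, merged genomic intervals with overlap/distance queries."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    # per input interval metadata (labels, test counts) prior to merging
    table: pd.DataFrame | None = None

    @classmethod
    def from_frame(cls, df: pd.DataFrame, round_to_grid: bool = True) -> "RegionSet":
        """Build from a frame with chrom/start/end (0-based half-open).

        Optional columns (method labels, n_tests) are kept in ``table``.
        Within-chromosome overlaps are merged for the density arithmetic.
        """
        df = df.copy()
        if round_to_grid:
            rounded = [round_10kb(s, e) for s, e in zip(df["start"], df["end"])]
            df[["start", "end"]] = rounded
        ivals = {}
        for chrom, grp in df.groupby("chrom"):
            arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
            arr = arr[np.argsort(arr[:, 0])]
            merged = []
            for s, e in arr:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            ivals[str(chrom)] = np.asarray(merged, dtype=np.int64)
        return cls(intervals=ivals, table=df)

    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum()
                       for arr in self.intervals.values()))

    def n_intervals(self) -> int:
        return int(sum(len(arr) for arr in self.intervals.values()))

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does each (chrom, pos) fall inside a region?"""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(len(pos), dtype=bool)
        for c, arr in self.intervals.items():
            sel = chrom == c
            if not sel.any() or not len(arr):
                continue
            idx = np.searchsorted(arr[:, 0], pos[sel], side="right") - 1
            ok = (idx >= 0) & (pos[sel] < arr[np.clip(idx, 0, None), 1])
            out[np.flatnonzero(sel)[ok]] = True
        return out

    def distance(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Distance (bp) from each position to the nearest region edge.

        Zero inside a region; +inf on chromosomes without regions.
        """
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), np.inf)
        for c, arr in self.intervals.items():
            sel = chrom == c
            if not sel.any() or not len(arr):
                continue
            p = pos[sel]
            idx = np.searchsorted(arr[:, 0], p, side="right") - 1
            inside = (idx >= 0) & (p < arr[np.clip(idx, 0, None), 1])
            d_prev = np.where(idx >= 0, p - arr[np.clip(idx, 0, None), 1] + 1, np.inf)
            nxt = np.clip(idx + 1, 0, len(arr) - 1)
            d_next = np.where(idx + 1 < len(arr), arr[nxt, 0] - p, np.inf)
            d = np.minimum(np.maximum(d_prev, 0), np.maximum(d_next, 0))
            d[inside] = 0.0
            out[np.flatnonzero(sel)] = d
        return out

    def mask_overlap_bp(self, mask: pd.DataFrame) -> tuple[int, int]:
        """(bp of mask inside regions, bp of mask outside regions)."""
        inside = 0
        total = 0
        for row in mask.itertuples():
            length = row.end - row.start
            total += length
            arr = self.intervals.get(str(row.chrom))
            if arr is None or not len(arr):
                continue
            o = (np.minimum(arr[:, 1], row.end)
                 - np.maximum(arr[:, 0], row.start))
            inside += int(o[o > 0].sum())
        return inside, total - inside


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Probability of >= a in the top-left cell given fixed margins
    (hypergeometric tail); the enrichment direction is deleterious (first
    column) in hitchhiking regions (first row).  Empty margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0 or a + b == 0 or a + c == 0 or b + d == 0 or c + d == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, n, a + c, a + b))


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class EnrichmentResult:
    del_hh: int
    neu_hh: int
    del_out: int
    neu_out: int
    cds_kb_hh: float
    cds_kb_out: float
    ratio_hh: float
    ratio_out: float
    fold: float
    fold_ci: tuple[float, float]
    z: float
    z_pvalue: float
    fisher_p: float

    @property
    def del_density_hh(self) -> float:
        return self.del_hh / self.cds_kb_hh if self.cds_kb_hh else float("nan")

    @property
    def del_density_out(self) -> float:
        return self.del_out / self.cds_kb_out if self.cds_kb_out else float("nan")

    @property
    def neu_density_hh(self) -> float:
        return self.neu_hh / self.cds_kb_hh if self.cds_kb_hh else float("nan")

    @property
    def neu_density_out(self) -> float:
        return self.neu_out / self.cds_kb_out if self.cds_kb_out else float("nan")


def fold_ci(a: int, b: int, c: int, d: int, level: float = 0.95) -> tuple[float, float]:
    """Normal CI on the log ratio-of-ratios (a/b)/(c/d)."""
    if min(a, b, c, d) == 0:
        return (float("nan"), float("nan"))
    log_fold = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = stats.norm.ppf(0.5 + level / 2)
    return (float(np.exp(log_fold - zq * se)), float(np.exp(log_fold + zq * se)))


def enrichment_from_counts(del_hh: int, neu_hh: int, del_out: int, neu_out: int,
                           cds_kb_hh: float = float("nan"),
                           cds_kb_out: float = float("nan"),
                           ci_level: float = 0.95) -> EnrichmentResult:
    """All contrast statistics from a 2x2 of DEL/NEU counts in/out."""
    ratio_hh = del_hh / neu_hh if neu_hh else float("nan")
    ratio_out = del_out / neu_out if neu_out else float("nan")
    fold = ratio_hh / ratio_out if neu_hh and neu_out and del_out else float("nan")
    z, zp = two_proportion_ztest(del_hh, del_hh + neu_hh, del_out, del_out + neu_out) \
        if (del_hh + neu_hh) and (del_out + neu_out) else (float("nan"), float("nan"))
    return EnrichmentResult(
        del_hh=del_hh, neu_hh=neu_hh, del_out=del_out, neu_out=neu_out,
        cds_kb_hh=cds_kb_hh, cds_kb_out=cds_kb_out,
        ratio_hh=ratio_hh, ratio_out=ratio_out, fold=fold,
        fold_ci=fold_ci(del_hh, neu_hh, del_out, neu_out, ci_level),
        z=z, z_pvalue=zp,
        fisher_p=fisher_one_sided(del_hh, neu_hh, del_out, neu_out))


def enrichment(snps: pd.DataFrame, regions: RegionSet,
               mask: pd.DataFrame, ci_level: float = 0.95) -> EnrichmentResult:
    """Deleterious/neutral contrast of SNPs inside vs outside regions.

    ``snps`` needs chrom/pos/call (DEL or NEU); densities are per kb of
    accessible aligned CDS (``mask``: chrom/start/end) on each side.
    """
    cds_in, cds_out = regions.mask_overlap_bp(mask)
    if cds_in <= 0 or cds_out <= 0:
        raise ValueError("accessible CDS must be nonzero inside and outside regions")
    inside = regions.contains(snps["chrom"].to_numpy(), snps["pos"].to_numpy())
    call = snps["call"].to_numpy()
    return enrichment_from_counts(
        int(((call == "DEL") & inside).sum()),
        int(((call == "NEU") & inside).sum()),
        int(((call == "DEL") & ~inside).sum()),
        int(((call == "NEU") & ~inside).sum()),
        cds_kb_hh=cds_in / 1000, cds_kb_out=cds_out / 1000, ci_level=ci_level)


def classify_freq(freq: np.ndarray,
                  classes: dict[str, tuple[float, float]] = FREQ_CLASSES) -> np.ndarray:
    """Frequency-class labels; boundaries are right-closed (lo, hi]."""
    freq = np.asarray(freq, dtype=float)
    out = np.full(len(freq), "", dtype=object)
    for name, (lo, hi) in classes.items():
        out[(freq > lo) & (freq <= hi)] = name
    return out


def freq_class_ratios(snps: pd.DataFrame, regions: RegionSet,
                      classes: dict[str, tuple[float, float]] = FREQ_CLASSES,
                      ci_level: float = 0.95) -> dict[str, EnrichmentResult]:
    """Per-frequency-class DEL/NEU enrichment in vs out of regions.

    SNPs with derived frequency outside (0, 1] are dropped (and counted via
    the returned classes' totals).  ``snps`` needs chrom/pos/call/freq.
    """
    labels = classify_freq(snps["freq"].to_numpy(), classes)
    inside = regions.contains(snps["chrom"].to_numpy(), snps["pos"].to_numpy())
    call = snps["call"].to_numpy()
    out = {}
    for name in classes:
        sel = labels == name
        out[name] = enrichment_from_counts(
            int(((call == "DEL") & inside & sel).sum()),
            int(((call == "NEU") & inside & sel).sum()),
            int(((call == "DEL") & ~inside & sel).sum()),
            int(((call == "NEU") & ~inside & sel).sum()),
            ci_level=ci_level)
    return out


def ihs_windows(ihs: pd.DataFrame, cutoff: float = 0.05,
                window: int = IHS_WINDOW,
                abs_cutoff: float = IHS_ABS_CUTOFF) -> tuple[pd.DataFrame, RegionSet]:
    """Empirical-outlier selection of 100-kb windows by |iHS| fraction.

    Windows are scored by the fraction of SNPs with |iHS| > 2, grouped into
    bins by SNP count (width 25, first bin [10, 25)), and the top
    ``cutoff`` fraction is taken separately within each bin.  Windows with
    fewer than 10 SNPs are excluded, as are bins with fewer than 100
    windows (400 at the 0.25% cutoff).  Returns (window table, selected
    regions merged into a RegionSet).
    """
    ihs = ihs.copy()
    ihs["win"] = (ihs["pos"] // window) * window
    grp = ihs.groupby(["chrom", "win"])
    tab = grp.agg(n_snps=("ihs", "size"),
                  n_extreme=("ihs", lambda x: int((np.abs(x) > abs_cutoff).sum())))
    tab = tab.reset_index().rename(columns={"win": "start"})
    tab["end"] = tab["start"] + window
    tab["fraction"] = tab["n_extreme"] / tab["n_snps"]
    tab["snp_bin"] = tab["n_snps"] // IHS_BIN_INCREMENT
    too_few_snps = tab["n_snps"] < IHS_MIN_SNPS
    min_windows = IHS_MIN_WINDOWS_STRICT if cutoff <= 0.0025 else IHS_MIN_WINDOWS
    bin_sizes = (tab[~too_few_snps].groupby("snp_bin")["fraction"]
                 .transform("size").reindex(tab.index, fill_value=0))
    tab["excluded"] = np.where(too_few_snps, "fewer_than_10_snps",
                               np.where(bin_sizes < min_windows,
                                        "bin_too_small", ""))
    tab["selected"] = False
    kept = tab[tab["excluded"] == ""]
    for _, idx in kept.groupby("snp_bin").groups.items():
        frac = tab.loc[idx, "fraction"]
        k = max(int(np.ceil(cutoff * len(frac))), 1)
        thresh = np.sort(frac.to_numpy())[-k]
        tab.loc[idx, "selected"] = frac >= thresh  # boundary ties included
    sel = tab[tab["selected"]]
    regions = RegionSet.from_frame(sel[["chrom", "start", "end"]],
                                   round_to_grid=False) if len(sel) else RegionSet()
    return tab, regions


def distance_bins(snps: pd.DataFrame, regions: RegionSet,
                  width: int = DISTANCE_BIN) -> pd.DataFrame:
    """DEL/NEU counts in 200-kb bands of distance to the nearest region.

    SNPs inside a region get the flagged region bin (d_k = NaN,
    in_region = True) and are excluded from the distance regression.
    Distances are SNP position to nearest region edge; d_k is the bin
    midpoint in Mb.
    """
    d = regions.distance(snps["chrom"].to_numpy(), snps["pos"].to_numpy())
    call = snps["call"].to_numpy()
    rows = []
    inside = d == 0
    rows.append({"bin": -1, "d_k": float("nan"), "in_region": True,
                 "DEL": int((call[inside] == "DEL").sum()),
                 "NEU": int((call[inside] == "NEU").sum())})
    outside = ~inside & np.isfinite(d)
    bins = (d[outside] // width).astype(int)
    for b in np.unique(bins):
        sel = bins == b
        rows.append({"bin": int(b), "d_k": (b + 0.5) * width / 1e6,
                     "in_region": False,
                     "DEL": int((call[outside][sel] == "DEL").sum()),
                     "NEU": int((call[outside][sel] == "NEU").sum())})
    return pd.DataFrame(rows)


def disease_overlap(alleles: pd.DataFrame, regions: RegionSet,
                    common_cutoff: float = DISEASE_COMMON_CUTOFF,
                    or_cutoff: float = 2.0) -> dict:
    """Hitchhiking : non-hitchhiking overlap ratios for disease alleles.

    ``alleles`` needs chrom/pos/category, optional freq (missing treated as
    0, i.e. rare) and odds_ratio.  Returns per-category in/out counts and
    ratios, pairwise one-sided Fisher tests between categories, a rank-sum
    test on allele frequencies in vs out, and the proportion of alleles
    with odds ratio > 2 in vs out with a Fisher test.
    """
    alleles = alleles.copy()
    if "freq" not in alleles:
        alleles["freq"] = np.nan
    alleles["freq"] = alleles["freq"].fillna(0.0)
    alleles["common"] = alleles["freq"] >= common_cutoff
    inside = regions.contains(alleles["chrom"].to_numpy(),
                              alleles["pos"].to_numpy())
    alleles["in_region"] = inside

    categories = {}
    skipped = []
    for cat, grp in alleles.groupby("category"):
        n_in = int(grp["in_region"].sum())
        n_out = int((~grp["in_region"]).sum())
        if n_in + n_out == 0:
            skipped.append(cat)
            continue
        categories[cat] = {
            "n_in": n_in, "n_out": n_out,
            "ratio": n_in / n_out if n_out else float("nan"),
        }
    pairwise = {}
    for c1, c2 in combinations(sorted(categories), 2):
        a, b = categories[c1]["n_in"], categories[c1]["n_out"]
        c, d = categories[c2]["n_in"], categories[c2]["n_out"]
        pairwise[(c1, c2)] = fisher_one_sided(a, b, c, d)

    f_in = alleles.loc[inside, "freq"]
    f_out = alleles.loc[~inside, "freq"]
    if len(f_in) and len(f_out):
        ranksum_p = float(stats.mannwhitneyu(
            f_in, f_out, alternative="two-sided").pvalue)
    else:
        ranksum_p = float("nan")

    result = {"categories": categories, "skipped": skipped,
              "pairwise_fisher": pairwise, "freq_ranksum_p": ranksum_p}

    if "odds_ratio" in alleles:
        has_or = alleles["odds_ratio"].notna()
        hi = alleles["odds_ratio"] > or_cutoff
        a = int((has_or & hi & inside).sum())
        b = int((has_or & ~hi & inside).sum())
        c = int((has_or & hi & ~inside).sum())
        d = int((has_or & ~hi & ~inside).sum())
        result["odds_ratio_gt2"] = {
            "prop_in": a / (a + b) if a + b else float("nan"),
            "prop_out": c / (c + d) if c + d else float("nan"),
            "fisher_p": fisher_one_sided(a, b, c, d),
        }
    return result
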