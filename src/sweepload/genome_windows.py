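"""Recombination-rate windowing and the logistic-regression analyses.

The genome is cut into non-overlapping 400-kb windows; each window's local
recombination rate (cM/Mb) is the genetic-map distance between its two most
distant SNPs divided by their physical distance.  Windows are dropped when
that SNP span is <= 360 kb, when the window lies within 10 Mb of a
centromere or telomere end, or when it contains no aligned coding sequence.
Retained windows are assigned to ten equal-sized bins by recombination rate.

Codons are stratified by the number of G/C nucleotides in the (ancestral)
human codon, j = 0..3, because both conservation and SNP density covary
with GC content.  The offset

    s_{i,j} = fdel_j * fcon_{i,j} / fcon_j

rescales the class-wide deleterious fraction ``fdel_j`` by the bin's
relative conservation density and enters the binomial GLMs as a fixed
logit offset, adjusting for differences in the number of potentially
deleterious sites.  Three models are fit on DEL successes out of DEL+NEU
trials:

    recombination:  logit(p) = logit(s_{i,j}) + b0 + b1 * r_i
    hitchhiking:    logit(p) = logit(s_{i,j,h}) + b0 + b1 * r_i + b2 * h
    distance:       logit(p) = b0 + b1 * d_k        (no offset)

The regression forms are this package's reconstruction of the analysis from
its verbal description; they are validated by parameter-recovery
simulations, not against any published coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

WINDOW_SIZE = 400_000
MIN_SNP_SPAN = 360_000
END_MARGIN = 10_000_000
N_BINS = 10
OFFSET_EPS = 1e-6
GC_CLASSES = (0, 1, 2, 3)


class DegenerateDesignError(ValueError):
    """The regression design is degenerate (e.g. only one group present)."""


@dataclass
class LogisticFit:
    model: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    offset: str
    converged: bool
    nobs: int
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)


def codon_gc_class(codon: str) -> int:
    """Number of G or C nucleotides in the codon (0..3)."""
    return sum(1 for b in codon.upper() if b in "GC")


def window_rec_rate(snp_pos: np.ndarray, snp_cm: np.ndarray) -> tuple[float, str]:
    """(rate in cM/Mb, exclusion reason) for one window's SNPs.

    The rate uses the two most physically distant SNPs with map values; the
    window is excluded when they are <= 360 kb apart.
    """
    snp_pos = np.asarray(snp_pos, dtype=float)
    snp_cm = np.asarray(snp_cm, dtype=float)
    if snp_pos.size < 2:
        return float("nan"), "fewer_than_two_snps"
    order = np.argsort(snp_pos)
    pos, cm = snp_pos[order], snp_cm[order]
    if (np.diff(cm) < 0).any():
        raise ValueError("genetic map must be non-decreasing with position")
    span = pos[-1] - pos[0]
    if span <= MIN_SNP_SPAN:
        return float("nan"), "snp_span_le_360kb"
    rate = (cm[-1] - cm[0]) / (span / 1e6)
    return float(rate), ""


def _overlap_bp(mask: pd.DataFrame, start: int, end: int) -> int:
    if not len(mask):
        return 0
    o = (np.minimum(mask["end"].to_numpy(), end)
         - np.maximum(mask["start"].to_numpy(), start))
    return int(o[o > 0].sum())


def build_windows(snps: pd.DataFrame, genetic_map: pd.DataFrame,
                  chrom_ends: pd.DataFrame, cds_mask: pd.DataFrame,
                  window_size: int = WINDOW_SIZE,
                  end_margin: int = END_MARGIN) -> pd.DataFrame:
    """Tile chromosomes into windows with rates and exclusion flags.

    ``snps`` needs chrom/pos; ``genetic_map`` chrom/pos/cm (cumulative cM,
    sorted by pos); ``chrom_ends`` chrom/start/end intervals marking
    centromere/telomere ends; ``cds_mask`` chrom/start/end accessible
    aligned CDS intervals (0-based half-open).
    """
    rows = []
    for chrom, cmap in genetic_map.groupby("chrom"):
        cmap = cmap.sort_values("pos")
        if (cmap["cm"].diff().dropna() < 0).any():
            raise ValueError(f"genetic map unsorted on {chrom}")
        chrom_len = int(cmap["pos"].max())
        csnp = snps[snps.chrom == chrom]
        pos = csnp["pos"].to_numpy()
        snp_cm = np.interp(pos, cmap["pos"], cmap["cm"])
        ends = chrom_ends[chrom_ends.chrom == chrom]
        mask = cds_mask[cds_mask.chrom == chrom]
        for start in range(0, chrom_len, window_size):
            end = start + window_size
            in_w = (pos >= start) & (pos < end)
            rate, reason = window_rec_rate(pos[in_w], snp_cm[in_w])
            near_end = any(
                start < e.end + end_margin and end > e.start - end_margin
                for e in ends.itertuples())
            cds_bp = _overlap_bp(mask, start, end)
            if near_end:
                reason = "near_chromosome_end"
            elif cds_bp == 0:
                reason = "no_aligned_cds"
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "rec_rate": rate, "cds_bp": cds_bp,
                         "excluded": bool(reason), "reason": reason})
    return pd.DataFrame(rows)


def assign_rec_bins(windows: pd.DataFrame, n_bins: int = N_BINS) -> pd.DataFrame:
    """Equal-sized recombination-rate bins (sizes differ by at most 1)."""
    kept = windows[~windows["excluded"]].copy()
    if len(kept) < n_bins:
        raise DegenerateDesignError("fewer retained windows than bins")
    order = np.argsort(kept["rec_rate"].to_numpy(), kind="stable")
    sizes = np.full(n_bins, len(kept) // n_bins)
    sizes[: len(kept) % n_bins] += 1
    bins = np.empty(len(kept), dtype=int)
    bins[order] = np.repeat(np.arange(1, n_bins + 1), sizes)
    kept["rec_bin"] = bins
    return kept


def assign_to_windows(df: pd.DataFrame, windows: pd.DataFrame,
                      cols: list[str]) -> pd.DataFrame:
    """Attach window columns ``cols`` to positioned rows (chrom, pos).

    Rows falling outside any retained window are dropped.
    """
    out = []
    for chrom, grp in df.groupby("chrom"):
        w = windows[windows.chrom == chrom].sort_values("start")
        if w.empty:
            continue
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        p = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        g = grp.loc[ok].copy()
        for c in cols:
            g[c] = w[c].to_numpy()[idx[ok]]
        out.append(g)
    return pd.concat(out) if out else df.iloc[0:0].assign(**{c: [] for c in cols})


def make_cells(windows: pd.DataFrame, snps: pd.DataFrame,
               codons: pd.DataFrame, by_h: bool = False) -> pd.DataFrame:
    """Aggregate into (rec_bin, gc_class[, h]) cells for the GLMs.

    ``windows`` must carry rec_bin (and h in {0,1} when ``by_h``); ``snps``
    chrom/pos/call/gc_class with call in {DEL, NEU}; ``codons``
    chrom/pos/gc_class/conserved for every aligned codon.
    """
    win_keys = ["rec_bin"] + (["h"] if by_h else [])
    if by_h:
        windows = windows[windows["h"].isin([0, 1])]
    snp_w = assign_to_windows(snps[snps["call"].isin(["DEL", "NEU"])],
                              windows, win_keys)
    cod_w = assign_to_windows(codons, windows, win_keys)
    r_by_bin = windows.groupby("rec_bin")["rec_rate"].mean()

    key_frames = windows[win_keys].drop_duplicates()
    rows = []
    for key in key_frames.itertuples(index=False):
        for j in GC_CLASSES:
            sel_s = snp_w["gc_class"] == j
            sel_c = cod_w["gc_class"] == j
            for col, val in zip(win_keys, key):
                sel_s &= snp_w[col] == val
                sel_c &= cod_w[col] == val
            row = {"rec_bin": key[0], "gc_class": j,
                   "r_i": float(r_by_bin[key[0]]),
                   "DEL": int((snp_w.loc[sel_s, "call"] == "DEL").sum()),
                   "NEU": int((snp_w.loc[sel_s, "call"] == "NEU").sum()),
                   "codons": int(sel_c.sum()),
                   "conserved_codons": int(cod_w.loc[sel_c, "conserved"].sum())}
            if by_h:
                row["h"] = key[1]
            rows.append(row)
    return pd.DataFrame(rows).sort_values(win_keys + ["gc_class"]).reset_index(drop=True)


def compute_offset(cells: pd.DataFrame, eps: float = OFFSET_EPS) -> pd.DataFrame:
    """Offset s_{i,j} = fdel_j * fcon_{i,j} / fcon_j per cell.

    Cells with no aligned codons are flagged missing and dropped from the
    model likelihoods.  fdel_j is the fraction of deleterious among tested
    nonsynonymous SNPs in GC class j; fcon_j is the mean of fcon_{i,j} over
    recombination bins.
    """
    cells = cells.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells["fcon_ij"] = np.where(
            cells["codons"] > 0,
            cells["conserved_codons"] / np.maximum(cells["codons"], 1), np.nan)
    fcon_j = cells.groupby("gc_class")["fcon_ij"].mean().rename("fcon_j")
    per_j = cells.groupby("gc_class")[["DEL", "NEU"]].sum()
    tot = per_j["DEL"] + per_j["NEU"]
    fdel_j = (per_j["DEL"] / tot.where(tot > 0)).rename("fdel_j")
    cells = cells.merge(fcon_j, on="gc_class", how="left")
    cells = cells.merge(fdel_j, on="gc_class", how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        s = cells["fdel_j"] * cells["fcon_ij"] / cells["fcon_j"]
    cells["s_ij"] = np.clip(s.fillna(eps), eps, 1 - eps)
    cells["missing"] = cells["codons"] <= 0
    return cells


def _fit_binomial(cells: pd.DataFrame, xcols: list[str], model_name: str,
                  offset_col: str | None = "s_ij") -> LogisticFit:
    cells = cells.loc[(cells["DEL"] + cells["NEU"]) > 0].copy()
    if len(cells) < len(xcols) + 1:
        raise DegenerateDesignError(f"{model_name}: too few informative cells")
    endog = cells[["DEL", "NEU"]].to_numpy(dtype=float)
    exog = sm.add_constant(cells[xcols].to_numpy(dtype=float),
                           has_constant="add")
    offset = None
    if offset_col is not None:
        s = cells[offset_col].to_numpy(dtype=float)
        offset = np.log(s / (1.0 - s))
    res = sm.GLM(endog, exog, family=sm.families.Binomial(), offset=offset).fit()
    if not res.converged:
        raise DegenerateDesignError(
            f"{model_name}: IRLS did not converge (possible separation)")
    names = ["beta0"] + [f"beta{k + 1}" for k in range(len(xcols))]
    ci = np.asarray(res.conf_int())
    return LogisticFit(
        model=model_name,
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        offset=f"logit({offset_col})" if offset_col else "none",
        converged=bool(res.converged),
        nobs=len(cells),
        conf_int={n: (float(ci[k, 0]), float(ci[k, 1]))
                  for k, n in enumerate(names)},
    )


def fit_recombination_model(cells: pd.DataFrame) -> LogisticFit:
    """DEL/(DEL+NEU) per (bin, GC-class) cell vs mean bin recombination rate.

    ``cells`` must carry DEL, NEU, r_i and s_ij (from
    :func:`compute_offset`); returns beta1 (per cM/Mb) with its Wald p.
    """
    cells = cells.loc[~cells["missing"]] if "missing" in cells else cells
    if cells["r_i"].nunique() < 2:
        raise DegenerateDesignError("recombination model needs >= 2 bins")
    return _fit_binomial(cells, ["r_i"], "recombination")


def fit_hitchhiking_model(cells: pd.DataFrame) -> LogisticFit:
    """Adds the hitchhiking indicator h to the recombination model (beta2)."""
    cells = cells.loc[~cells["missing"]] if "missing" in cells else cells
    cells = cells[cells["h"].isin([0, 1])]
    if cells["h"].nunique() < 2:
        raise DegenerateDesignError("hitchhiking model needs h=0 and h=1 cells")
    return _fit_binomial(cells, ["r_i", "h"], "hitchhiking")


def fit_distance_model(binned: pd.DataFrame) -> LogisticFit:
    """Deleterious fraction vs distance (Mb) to the nearest sweep region.

    ``binned`` carries per-distance-bin DEL, NEU and d_k (Mb); SNPs inside
    regions are excluded upstream.  Plain logistic fit, no offset.
    """
    informative = binned.loc[(binned["DEL"] + binned["NEU"]) > 0]
    if len(informative) < 2:
        raise DegenerateDesignError("distance model needs >= 2 informative bins")
    return _fit_binomial(informative, ["d_k"], "distance", offset_col=None)


def bgc_filter(snps: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove SNPs confounded by GC-biased gene conversion.

    Drops A/T -> G/C mutating SNPs (the transmission direction favoured by
    biased gene conversion), SNPs in GC-class-0 codons, and SNPs with
    unknown ancestral state.  Requires columns ancestral, derived, gc_class.
    """
    anc = snps["ancestral"].str.upper()
    der = snps["derived"].str.upper()
    known = anc.isin(list("ACGT")) & der.isin(list("ACGT"))
    at_to_gc = anc.isin(["A", "T"]) & der.isin(["G", "C"])
    gc0 = snps["gc_class"] == 0
    keep = known & ~at_to_gc & ~gc0
    counts = {
        "unknown_ancestral": int((~known).sum()),
        "at_to_gc": int((known & at_to_gc).sum()),
        "gc_class_0": int((known & ~at_to_gc & gc0).sum()),
        "kept": int(keep.sum()),
    }
    return snps.loc[keep].copy(), counts
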