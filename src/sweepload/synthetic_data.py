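"""Synthetic genomes with known ground truth for every pipeline stage.

Generates the full input bundle the analyses consume — gene/codon
annotation, accessible-CDS mask, genetic map, centromere/telomere ends,
sweep-region intervals with per-method labels, SNP tables with
class-specific allele-frequency spectra, codon alignments evolved along a
random phylogeny, per-SNP iHS scores, and disease-allele tables — plus
truth sidecars that the pipeline never reads.

Deleterious enrichment inside sweep regions is produced by thinning
neutral and synonymous SNPs by 1/f (hitchhiking removes neutral variation
while the deleterious count stays roughly constant), so the true
deleterious/neutral fold between regions and background equals ``f``.

Allele-frequency spectra are discretised Beta distributions — simple,
controllable shapes with the deleterious class skewed rare — not diffusion
solutions; every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lrt_classifier as lrt

IHS_METHODS = ("iHS", "Rsb", "CLR", "TajD1", "TajD2", "FayWuH", "XPEHH",
               "Fst", "LDD")


@dataclass
class SynthConfig:
    """Study-like synthetic-genome conditions.

    Defaults give two 60-Mb chromosomes with one 500-codon gene every
    150 kb, ~29% of nonsynonymous SNPs deleterious, a 1.5-fold true
    deleterious/neutral enrichment inside sweep regions, and a 1.2 cM/Mb
    baseline map with hotspots.
    """

    n_chroms: int = 2
    chrom_length: int = 60_000_000
    gene_spacing: int = 150_000
    gene_codons: int = 500
    accessible_fraction: float = 0.8
    conserved_frac_by_gc: tuple[float, ...] = (0.25, 0.40, 0.55, 0.65)
    n_syn_snps: int = 12_000
    n_nonsyn_snps: int = 12_000
    del_fraction: float = 0.29
    del_freq_shape: tuple[float, float] = (0.2, 3.0)
    neu_freq_shape: tuple[float, float] = (0.25, 0.8)
    n_sweep_regions: int = 25
    sweep_width: int = 600_000
    enrichment_fold: float = 1.5
    map_baseline: float = 1.2  # cM/Mb
    n_hotspots: int = 30
    hotspot_multiplier: float = 8.0
    hotspot_width: int = 50_000
    n_taxa: int = 32
    n_eutherians: int = 20
    ds_total: float = 12.2
    conserved_omega: float = 0.05
    neutral_omega: float = 1.0
    n_alignment_genes: int = 40
    ihs_snp_spacing: int = 2_000
    ihs_sweep_scale: float = 1.8
    n_disease: dict = field(default_factory=lambda: {
        "omim_variant": 600, "morbid_gene": 1500,
        "gwas": 900, "gwas_nonsyn": 120})
    disease_in_region_freq_shift: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.accessible_fraction, self.del_fraction,
                     *self.conserved_frac_by_gc):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        if self.gene_codons * 3 > self.gene_spacing:
            raise ValueError("genes longer than their spacing")
        if self.gene_codons < 1:
            raise ValueError("need at least one codon per gene")


@dataclass
class SyntheticGenome:
    genes: pd.DataFrame  # chrom, start, end, gene_id, n_codons
    codons: pd.DataFrame  # chrom, pos, gene_id, codon_idx, codon, gc_class, conserved
    mask: pd.DataFrame  # accessible CDS (chrom, start, end)
    genetic_map: pd.DataFrame  # chrom, pos, cm
    map_snps: pd.DataFrame  # genome-wide SNP positions for window rates
    chrom_ends: pd.DataFrame  # telomere intervals
    regions: pd.DataFrame  # sweep regions: chrom, start, end, methods, n_tests
    config: SynthConfig


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def make_genome(cfg: SynthConfig) -> SyntheticGenome:
    """Annotation, mask, map, chromosome ends and sweep regions."""
    rng = _rng(cfg, 1)
    codon_arr = np.array(lrt.CODONS)
    gc_of = np.array([sum(b in "GC" for b in c) for c in lrt.CODONS])
    cons_p = np.asarray(cfg.conserved_frac_by_gc)

    genes, codon_frames, mask_rows = [], [], []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        gid = 0
        for start in range(cfg.gene_spacing // 2, cfg.chrom_length - cfg.gene_spacing,
                           cfg.gene_spacing):
            gene_id = f"{chrom}_g{gid:04d}"
            end = start + cfg.gene_codons * 3
            genes.append({"chrom": chrom, "start": start, "end": end,
                          "gene_id": gene_id, "n_codons": cfg.gene_codons})
            ids = rng.integers(0, len(codon_arr), size=cfg.gene_codons)
            gc = gc_of[ids]
            conserved = rng.random(cfg.gene_codons) < cons_p[gc]
            codon_frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": start + 3 * np.arange(cfg.gene_codons),
                "gene_id": gene_id,
                "codon_idx": np.arange(cfg.gene_codons),
                "codon": codon_arr[ids],
                "gc_class": gc,
                "conserved": conserved,
            }))
            # accessible CDS: central accessible_fraction of the gene
            trim = int((end - start) * (1 - cfg.accessible_fraction) / 2)
            mask_rows.append({"chrom": chrom, "start": start + trim,
                              "end": end - trim})
            gid += 1

    # genetic map: baseline rate with multiplicative hotspots, 10-kb knots
    map_rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        knots = np.arange(0, cfg.chrom_length + 1, 10_000)
        rate = np.full(len(knots) - 1, cfg.map_baseline)
        centers = rng.integers(0, cfg.chrom_length, size=cfg.n_hotspots)
        for c in centers:
            hit = (knots[:-1] >= c - cfg.hotspot_width // 2) & \
                  (knots[:-1] < c + cfg.hotspot_width // 2)
            rate[hit] *= cfg.hotspot_multiplier
        cm = np.concatenate([[0.0], np.cumsum(rate * 10_000 / 1e6)])
        map_rows.append(pd.DataFrame({"chrom": chrom, "pos": knots, "cm": cm}))

    # genome-wide SNP positions (HapMap-like density) for window rates
    map_snp_rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n = cfg.chrom_length // 2_000
        pos = np.sort(rng.integers(0, cfg.chrom_length, size=n))
        map_snp_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))

    ends = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        ends.append({"chrom": chrom, "start": 0, "end": 10_000})
        ends.append({"chrom": chrom, "start": cfg.chrom_length - 10_000,
                     "end": cfg.chrom_length})

    region_rows = []
    for k in range(cfg.n_sweep_regions):
        chrom = f"chr{rng.integers(1, cfg.n_chroms + 1)}"
        start = int(rng.integers(0, cfg.chrom_length - cfg.sweep_width))
        n_tests = int(rng.integers(1, 10))
        methods = ",".join(sorted(rng.choice(IHS_METHODS, size=n_tests,
                                             replace=False)))
        region_rows.append({"chrom": chrom, "start": start,
                            "end": start + cfg.sweep_width,
                            "methods": methods, "n_tests": n_tests})

    return SyntheticGenome(
        genes=pd.DataFrame(genes),
        codons=pd.concat(codon_frames, ignore_index=True),
        mask=pd.DataFrame(mask_rows),
        genetic_map=pd.concat(map_rows, ignore_index=True),
        map_snps=pd.concat(map_snp_rows, ignore_index=True),
        chrom_ends=pd.DataFrame(ends),
        regions=pd.DataFrame(region_rows),
        config=cfg,
    )


def _in_regions(genome: SyntheticGenome, chrom: np.ndarray,
                pos: np.ndarray) -> np.ndarray:
    from .hh_enrichment import RegionSet
    rs = RegionSet.from_frame(genome.regions, round_to_grid=False)
    return rs.contains(chrom, pos)


def _pick_change(codon_id: int, synonymous: bool,
                 rng: np.random.Generator) -> tuple[str, str, str, str] | None:
    """(ancestral codon, derived codon, ancestral base, derived base)."""
    mask = lrt.SYN_MASK if synonymous else lrt.NONSYN_MASK
    nbrs = np.flatnonzero(mask[codon_id])
    if not len(nbrs):
        return None
    j = int(rng.choice(nbrs))
    anc, der = lrt.CODONS[codon_id], lrt.CODONS[j]
    for a, d in zip(anc, der):
        if a != d:
            return anc, der, a, d
    return None


def make_snps(cfg: SynthConfig, genome: SyntheticGenome) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP table plus a truth sidecar (never read by the pipeline).

    SNPs are placed on codon positions; deleterious SNPs live in conserved
    codons, and inside sweep regions neutral and synonymous SNPs are
    thinned by 1/f so the true deleterious/neutral fold equals f.
    """
    rng = _rng(cfg, 2)
    cod = genome.codons
    codon_id = cod["codon"].map(lrt.CODON_INDEX).to_numpy()
    conserved = cod["conserved"].to_numpy()

    n_del = int(round(cfg.n_nonsyn_snps * cfg.del_fraction))
    n_neu = cfg.n_nonsyn_snps - n_del
    picks = {
        "DEL": (rng.choice(np.flatnonzero(conserved), size=n_del, replace=False), False),
        "NEU": (rng.choice(np.flatnonzero(~conserved), size=n_neu, replace=False), False),
        "SYN": (rng.choice(len(cod), size=cfg.n_syn_snps, replace=False), True),
    }
    rows = []
    for call, (idx, synonymous) in picks.items():
        a, b = cfg.del_freq_shape if call == "DEL" else cfg.neu_freq_shape
        freqs = rng.beta(a, b, size=len(idx))
        for i, f in zip(idx, freqs):
            change = _pick_change(int(codon_id[i]), synonymous, rng)
            if change is None:
                continue
            anc_codon, der_codon, anc, der = change
            rows.append({
                "chrom": cod["chrom"].iat[i], "pos": int(cod["pos"].iat[i]),
                "ancestral": anc, "derived": der,
                "ancestral_codon": anc_codon, "derived_codon": der_codon,
                "freq": float(np.clip(f, 1e-4, 1.0)),
                "site_class": "SYN" if synonymous else "NONSYN",
                "call": call if call != "SYN" else "NA",
                "gene_id": cod["gene_id"].iat[i],
                "codon_idx": int(cod["codon_idx"].iat[i]),
                "gc_class": int(cod["gc_class"].iat[i]),
                "true_call": call,
            })
    snps = pd.DataFrame(rows).drop_duplicates(["chrom", "pos"])

    inside = _in_regions(genome, snps["chrom"].to_numpy(), snps["pos"].to_numpy())
    thin = inside & snps["true_call"].isin(["NEU", "SYN"]).to_numpy() \
        & (rng.random(len(snps)) > 1.0 / cfg.enrichment_fold)
    snps = snps.loc[~thin].reset_index(drop=True)

    truth = snps[["chrom", "pos", "true_call"]].copy()
    snps = snps.drop(columns="true_call")
    return snps, truth


def make_tree(cfg: SynthConfig) -> tuple[str, list[str], list[str]]:
    """Random bifurcating phylogeny as newick; (newick, taxa, eutherians).

    Taxon 'human' is the first eutherian.  Branch lengths are exponential;
    absolute scale is irrelevant because the classifier rescales the tree
    to its synonymous length.
    """
    rng = _rng(cfg, 3)
    taxa = ["human"] + [f"euth{i:02d}" for i in range(2, cfg.n_eutherians + 1)]
    taxa += [f"outgroup{i:02d}" for i in range(cfg.n_eutherians + 1, cfg.n_taxa + 1)]
    nodes = [f"{t}:{rng.exponential(0.4):.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (f"({nodes[i]},{nodes[j]}):{rng.exponential(0.4):.6f}")
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return newick, taxa, taxa[: cfg.n_eutherians]


def make_alignments(cfg: SynthConfig, genome: SyntheticGenome
                    ) -> tuple[dict[str, np.ndarray], lrt.ScaledTree,
                               list[str], pd.DataFrame]:
    """Codon alignments for a subset of genes evolved along the tree.

    Per-site omega follows the annotation truth: conserved codons evolve at
    ``conserved_omega``, others at ``neutral_omega``.  Returns (gene ->
    tip-state matrix, scaled tree, taxon order, truth table of omegas).
    """
    newick, taxa, _ = make_tree(cfg)
    tree = lrt.ScaledTree(newick, ds_total=cfg.ds_total)
    rng = _rng(cfg, 4)
    gene_ids = genome.genes["gene_id"].iloc[: cfg.n_alignment_genes]
    alignments: dict[str, np.ndarray] = {}
    truth_rows = []
    for gene_id in gene_ids:
        cod = genome.codons[genome.codons["gene_id"] == gene_id]
        omegas = np.where(cod["conserved"], cfg.conserved_omega, cfg.neutral_omega)
        states = np.empty((tree.n_tips, len(cod)), dtype=np.int64)
        for om in np.unique(omegas):
            cols = np.flatnonzero(omegas == om)
            states[:, cols] = lrt.simulate_columns(tree, float(om), len(cols), rng)
        alignments[gene_id] = states
        truth_rows.append(pd.DataFrame({
            "gene_id": gene_id, "codon_idx": cod["codon_idx"].to_numpy(),
            "omega": omegas}))
    return alignments, tree, tree.taxon_labels, pd.concat(truth_rows, ignore_index=True)


def alignment_to_fasta(states: np.ndarray, taxa: list[str]) -> dict[str, str]:
    """Tip-state matrix -> species -> concatenated codon sequence."""
    codon_arr = np.array(lrt.CODONS)
    return {sp: "".join(codon_arr[states[i]]) for i, sp in enumerate(taxa)}


def make_scores_and_diseases(cfg: SynthConfig, genome: SyntheticGenome
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP iHS scores and disease-allele tables with truth manifests.

    |iHS| is N(0,1) outside sweep regions and scaled by ``ihs_sweep_scale``
    inside; disease alleles get an in-region shift of their frequency
    distribution.
    """
    rng = _rng(cfg, 5)
    rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = np.arange(cfg.ihs_snp_spacing // 2, cfg.chrom_length,
                        cfg.ihs_snp_spacing)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    ihs = pd.concat(rows, ignore_index=True)
    inside = _in_regions(genome, ihs["chrom"].to_numpy(), ihs["pos"].to_numpy())
    scale = np.where(inside, cfg.ihs_sweep_scale, 1.0)
    ihs["ihs"] = rng.normal(0.0, 1.0, size=len(ihs)) * scale
    ihs["in_sweep"] = inside

    disease_rows = []
    for category, n in cfg.n_disease.items():
        chrom = np.array([f"chr{c}" for c in
                          rng.integers(1, cfg.n_chroms + 1, size=n)])
        pos = rng.integers(0, cfg.chrom_length, size=n)
        freq = rng.beta(0.3, 2.0, size=n)
        missing = rng.random(n) < 0.1
        freq = np.where(missing, np.nan, freq)
        inside = _in_regions(genome, chrom, pos)
        freq = np.where(inside & ~missing,
                        np.clip(freq + cfg.disease_in_region_freq_shift, 0, 1),
                        freq)
        odds = np.where(rng.random(n) < 0.5, np.nan,
                        np.exp(rng.normal(0.3, 0.5, size=n)))
        disease_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "category": category,
            "freq": freq, "odds_ratio": odds}))
    return ihs, pd.concat(disease_rows, ignore_index=True)
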