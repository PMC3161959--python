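# Methods

`sweepload` studies how positive selection (genetic hitchhiking) reshapes
linked deleterious polymorphism. It has three computational layers — a
forward Wright-Fisher sweep simulator, a conservation-based classifier of
nonsynonymous SNPs, and genome-scale enrichment statistics — plus a
synthetic-data generator that produces every pipeline input with known
ground truth. This note records the models, the parameters that matter,
the numerical choices, and the design decisions taken where the design was
genuinely open.

## Wright-Fisher sweep simulator (`wf_sim`, `sfs_stats`)

**Model.** A population of `N` diploids (2N chromosomes), discrete
generations, infinite-sites mutation on the continuous interval [0, 1).
Three mutation classes: neutral, deleterious and advantageous. Per
generation:

1. Diploid fitness is multiplicative over sites: `1 + h s` per heterozygous
   site, `1 + s` per homozygous site, with a single dominance coefficient
   `h = 0.5` by default.
2. Each of the 2N offspring chromosomes picks a parent individual with
   probability proportional to fitness and receives one gamete; by default
   the gamete copies one parental chromosome chosen fairly.
3. A Poisson(`rho`) number of crossover events occurs population-wide
   (`rho = N r`, with `r` the per-individual recombination rate); each
   event is assigned to a uniformly chosen offspring gamete at a uniform
   breakpoint. Multiple events on the same gamete are applied as
   successive switch points. Only the population-level event rate is part
   of the model definition; the per-gamete assignment rule is our choice
   and keeps per-meiosis cost O(1) at the stated rate. Recombination is
   applied during gamete formation (i.e. after parent selection); whether
   it conceptually precedes or follows selection within a generation does
   not change the sampling distribution here because crossovers only
   re-combine the two chromosomes of the already-chosen parent.
4. Poisson(2N·u_x) new mutations per class arise at uniform positions on
   uniformly chosen offspring chromosomes, `u_x = theta_x / 4N`. Position
   collisions (probability ~0 with 64-bit uniforms) are resolved by
   redrawing.
5. Mutations reaching count 2N are stripped from chromosomes and logged as
   fixed. Relative fitness is invariant to a factor common to all
   individuals, so stripping never changes offspring sampling.

**Parameters** (population-scaled, so dynamics are invariant to `N`):
`theta_n = 4Nu_n` and `theta_d = 4Nu_d` (default 70 each), `gamma_d = 4Ns_d`
(default −10), `gamma_a = 4Ns_a` (default +100), `theta_a = 4Nu_a`
(recurrent mode, default 0.5 when used), `h = 0.5`, burn-in 20N
generations, samples of 100 chromosomes. These defaults are the study
conditions for all simulation-based checks.

**Sweep regimes.** Single-sweep mode snapshots the burned-in population,
injects one advantageous mutation at position 0.5 at count 1, and iterates
until it fixes or is lost; on loss the exact pre-injection state is
restored and a fresh attempt is made (cap 10,000, configurable), so the
returned sample is conditioned on fixation. A matched pre-sweep sample is
drawn from the snapshot. Recurrent mode runs the burn-in without the
advantageous influx, then switches it on and samples every N generations,
regardless of whether a sweep is in progress at a sampling time.

**Estimators.** From the unfolded sample spectrum, `theta_W = S / a_n`,
`theta_pi = sum_i S_i 2i(n−i)/(n(n−1))`, `theta_H = sum_i S_i 2i^2/(n(n−1))`.
Sites fixed in the sample (count n) are substitutions, not polymorphisms,
and are excluded. The deleterious/neutral ratio is aggregated over
replicates as a ratio of replicate means: per-replicate ratios are
undefined whenever a replicate's neutral theta is zero, while the ratio of
means is stable.

**Problem sizes.** Tests and the acceptance script run the simulator at
reduced scale with the scaled parameters held fixed: `N = 200` for the
neutral-equilibrium check (50 replicates) and `N = 100` for the sweep
direction checks (burn-in 20N throughout). Since `theta`, `gamma` and
`rho` are population-scaled, the reduced-`N` runs probe the same dynamical
regime with more drift noise, which the replicate counts absorb. The
single-sweep contrast uses `rho = 1` as the intermediate recombination
rate of the default grid (0, 0.1, 1, 10, 100 population events per
generation); at `rho = 0` a completed sweep leaves almost no neutral
variation, at high `rho` linked effects vanish.

## Conservation classifier (`lrt_classifier`)

**Model.** Codon columns evolve over the 61 sense codons with uniform
stationary frequencies; single-nucleotide exchanges occur at rate 1 when
synonymous and `omega` when nonsynonymous; stop codons and
multi-nucleotide exchanges are disallowed. This is deliberately the
simplest process consistent with the dN = dS vs dN-free contrast; it omits
empirical codon frequencies and among-site rate variation, so genome-wide
deleterious fractions from richer codon models are not comparable and
are not asserted anywhere. Branch lengths are rescaled once per tree so
the tree-wide synonymous length equals `ds_total` (default 12.2
substitutions/site, a fixed input). Under uniform frequencies the rate
matrix is symmetric, so likelihoods use one eigendecomposition per omega
and matrix-vector products per branch (Felsenstein pruning with per-node
rescaling).

**Test.** Null: `omega = 1`. Alternative: `omega` free on [1e-4, 10].
`2 (lnL_alt − lnL_null)` is referred to chi-square with 1 df. A codon is
*conserved* when p < 0.001 (strict; p exactly 0.001 is not conserved) and
`omega_hat < 1` (the per-site-normalised dN/dS of this process equals
omega, so "dN < dS" is `omega_hat < 1`). A nonsynonymous SNP is
*deleterious* when its codon is conserved and the derived amino acid is
absent from the non-human eutherian rows; columns with fewer than 10
aligned eutherians (human included in the count) are *untestable*.
Because the conserved call is directional (p < 0.001 **and** omega_hat < 1),
its realised false-positive rate under omega = 1 is at most the nominal
0.001 — asymptotically about half of it, since the significant statistics
split between omega_hat above and below 1.

**Optimisation.** The scalar path (`lrt_site`) brackets on a 13-point
log-grid and refines with bounded Brent (xatol 1e-5 in log10 omega,
~1e-6 in lnL). The batched path (`lrt_sites`) evaluates all sites on a
33-point log grid, refines each site's best bracket on a 17-point local
grid (sites grouped by bracket so every evaluation stays vectorised), and
interpolates the peak parabolically; its lnL error is ~1e-4, negligible at
the 10.83 statistic threshold. The likelihood machinery is identical in
both paths; only the optimiser resolution differs.

## Genome windows and regressions (`genome_windows`)

400-kb windows; the window rate (cM/Mb) is the map distance between its
two most physically distant SNPs over their physical distance. Windows are
excluded when that span is ≤ 360 kb, within 10 Mb of a
centromere/telomere end, or without aligned coding sequence. Retained
windows go into ten equal-sized recombination bins (sizes differ by at
most one). Codons are stratified by G/C count j = 0..3 of the ancestral
human codon.

The offset `s_{i,j} = fdel_j · fcon_{i,j} / fcon_j` (clipped to
[1e-6, 1−1e-6]) is the GC-class deleterious fraction rescaled by the
bin's relative conservation density. The regression forms used here —

    recombination:  logit(p_{i,j})   = logit(s_{i,j})   + b0 + b1 r_i
    hitchhiking:    logit(p_{i,j,h}) = logit(s_{i,j,h}) + b0 + b1 r_i + b2 h
    distance:       logit(p_k)       = b0 + b1 d_k

with DEL successes out of DEL+NEU trials per cell — are this package's
own construction (binomial GLM, fixed logit offset, linear terms). They
are validated by parameter-recovery simulations and by agreement with an
independent IRLS implementation to 1e-6, never against externally
reported coefficients. `r_i` enters in cM/Mb;
distances are SNP-to-nearest-region-edge, binned in 200-kb bands with
`d_k` the bin midpoint in Mb. Hitchhiking windows require overlap with
regions found by ≥ 3 tests (h = 1) vs no overlap (h = 0); others are
dropped. The biased-gene-conversion filter removes A/T→G/C mutating SNPs,
SNPs in GC-class-0 codons, and SNPs with unknown ancestral state.

## Enrichment contrasts (`hh_enrichment`)

Region boundaries are rounded to the 10-kb grid containment-preservingly
(start down, end up) — nearest-rounding could drop SNPs the original
interval contained — then overlapping intervals are merged for density
arithmetic. Densities are per kb of accessible aligned CDS on each side.
The fold is the ratio of deleterious/neutral ratios in vs out;
significance comes from a one-sided Fisher exact test (hypergeometric
upper tail, enrichment of deleterious inside regions) and a pooled
two-proportion z-test. The fold CI is the normal interval on the log
ratio-of-ratios (se = sqrt(1/a+1/b+1/c+1/d)); the level is configurable
(0.95 default, 0.90 for figure-style bars); the bounds are not asserted
to match any externally reported interval.

Allele-frequency classes are right-closed: rare (0, 0.008],
intermediate (0.008, 0.059], common (0.059, 1]. Disease alleles use a 5%
cutoff, with missing frequencies set to 0 (rare). iHS windows are 100-kb,
scored by the fraction of SNPs with |iHS| > 2, binned by SNP count in
increments of 25, with per-bin empirical cutoffs; windows with < 10 SNPs
and bins with < 100 windows (< 400 at the 0.25% cutoff) are excluded.
Category comparisons are reported per-comparison without multiplicity
correction, mirroring per-comparison reporting conventions; a Bonferroni
flag is available to users.

## Poisson cluster scan (`cluster_scan`)

1-Mb windows, 0.5-Mb step. The genome-wide deleterious rate per
accessible-CDS kb is always computed from the input data, never supplied.
Windows with k ≥ 2 deleterious SNPs are ranked by the Poisson upper tail
P(X ≥ k) at `lambda = rate × CDS kb`; the *smallest* p values are
selected — ranking by significance is the only reading consistent with a
small-p selection threshold — taking the top 2% of eligible windows with
boundary ties included. Selected windows that
overlap or share a boundary are merged into one region keeping the
chain's minimum p and the union coordinates; merging is idempotent and
order-independent.

## Synthetic data (`synthetic_data`)

The generator emulates the input formats of the real analyses — SNP
tables, codon annotation, accessible-CDS mask, genetic map (baseline 1.2
cM/Mb with hotspots), genome-wide map-SNP positions, sweep-region
intervals labeled by up to nine methods, codon alignments on a random
32-taxon tree (20 eutherians), iHS tracks and disease-allele tables —
with truth sidecars the pipeline never reads. Defaults: two 60-Mb
chromosomes, one 500-codon gene per 150 kb, 12,000 synonymous and 12,000
nonsynonymous SNPs with 29% of nonsynonymous deleterious, deleterious
frequencies Beta(0.2, 3) vs neutral Beta(0.25, 0.8) (so deleterious SNPs
skew rare), 25 sweep regions of 600 kb with true deleterious/neutral fold
f = 1.5 produced by *thinning* neutral and synonymous SNPs inside regions
by 1/f (hitchhiking removes neutral variation; the deleterious count
stays roughly constant), and |iHS| scaled by 1.8 inside sweeps.

What it does **not** emulate: linkage disequilibrium (iHS values are
synthetic scores, not computed from haplotypes), demography, a
diffusion-consistent frequency spectrum (the Beta spectra are
controllable shapes, not population-genetic solutions), or correlation
between recombination rate and deleterious density (absent by default, so
a near-zero recombination coefficient on default synthetic data is the
correct answer). Passing tests on these data demonstrate that the
statistics recover planted structure of the stated kind; they do not
certify behaviour on real human data.

## Degenerate inputs and tie-breaks

Zero denominators in class ratios are flagged missing and excluded with a
count; empty Fisher margins give p = 1 by convention; GLM cells with no
aligned codons are dropped from the likelihood; separation or
non-convergence raises a degenerate-design error rather than returning
coefficients; the iHS per-bin cutoff includes ties at the threshold; the
2% scan cutoff is computed on eligible (k ≥ 2) windows only, ties
included.

## Known limitations

The codon model's uniform frequencies understate compositional bias, so
absolute conservation calls on real alignments would differ from richer
models (relative contrasts are the target here). The simulator tracks a
single linear chromosome without gene structure, so simulated
"deleterious polymorphism" maps onto nonsynonymous SNPs only by analogy.
The regression offset and equation forms are this package's own design,
documented above, and should be treated as such.
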