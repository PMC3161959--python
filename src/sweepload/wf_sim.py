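"""Forward-time Wright-Fisher simulation of hitchhiking with linked selection.

Simulates a population of ``N`` diploids (2N chromosomes) on a continuous
chromosome in [0, 1) under the infinite-sites model.  Three mutation classes
are tracked: neutral, deleterious (scaled strength ``gamma_d = 4N s_d < 0``)
and advantageous (``gamma_a = 4N s_a > 0``).  Fitness is multiplicative over
sites, ``1 + h s`` per heterozygous site and ``1 + s`` per homozygous site.
Recombination happens as a population-level Poisson number of crossover
events per generation, each applied to one uniformly chosen offspring gamete
at a uniform breakpoint.

Two sweep regimes are provided: a single hitchhiking event conditioned on
fixation of an advantageous mutation injected at the chromosome centre, and
recurrent sweeps driven by a constant influx of advantageous mutations with
samples drawn every N generations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

NEUTRAL = 0
DELETERIOUS = 1
ADVANTAGEOUS = 2
CLASS_NAMES = {NEUTRAL: "neutral", DELETERIOUS: "deleterious", ADVANTAGEOUS: "advantageous"}


class DegenerateParametersError(ValueError):
    """All individuals have non-positive fitness: no parent can be drawn."""


class SweepAttemptsExceededError(RuntimeError):
    """Fixation conditioning exceeded the configured re-injection cap."""


@dataclass
class SimParams:
    """Scaled Wright-Fisher parameters.

    All mutation and selection parameters are population-scaled (``4Nu`` and
    ``4Ns``), so dynamics are comparable across population sizes; ``N`` sets
    the time scale and drift variance.
    """

    N: int = 1000
    theta_n: float = 70.0
    theta_d: float = 70.0
    theta_a: float = 0.0
    gamma_d: float = -10.0
    gamma_a: float = 100.0
    h: float = 0.5
    rho: float = 0.0  # population crossover events per generation (N * r)
    burn_in: int | None = None  # default 20N
    sample_n: int = 100
    n_reps: int = 1
    seed: int | None = None
    max_sweep_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if min(self.theta_n, self.theta_d, self.theta_a) < 0:
            raise ValueError("theta parameters must be >= 0")
        if self.gamma_d > 0 or self.gamma_a < 0:
            raise ValueError("require gamma_d <= 0 <= gamma_a")
        if not 0 <= self.h <= 1:
            raise ValueError("dominance h must be in [0, 1]")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.sample_n > 2 * self.N:
            raise ValueError("sample_n must be <= 2N")

    @property
    def n_burn_in(self) -> int:
        return 20 * self.N if self.burn_in is None else self.burn_in

    @property
    def s_d(self) -> float:
        return self.gamma_d / (4 * self.N)

    @property
    def s_a(self) -> float:
        return self.gamma_a / (4 * self.N)

    def s_of_class(self, mclass: int) -> float:
        if mclass == DELETERIOUS:
            return self.s_d
        if mclass == ADVANTAGEOUS:
            return self.s_a
        return 0.0

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in self.__dataclass_fields__})


@dataclass
class FixedMutation:
    id: int
    position: float
    mclass: int
    birth_gen: int
    fixed_gen: int


@dataclass
class Population:
    """2N haploid chromosomes as a dense 0/1 genotype matrix.

    Columns are live (segregating) mutations; per-column metadata arrays run
    parallel to the matrix.  Chromosomes ``2i`` and ``2i+1`` form diploid
    individual ``i``.  Mutations that reach count 2N are stripped from the
    matrix and appended to ``fixed`` so relative fitness is unaffected
    (a factor common to all individuals cancels in parent sampling).
    """

    geno: np.ndarray  # (2N, M) uint8
    positions: np.ndarray  # (M,) float64, unique
    mclasses: np.ndarray  # (M,) int8
    sel: np.ndarray  # (M,) float64 selection coefficient per homozygote
    ids: np.ndarray  # (M,) int64
    births: np.ndarray  # (M,) int64
    generation: int = 0
    next_id: int = 0
    fixed: list[FixedMutation] = field(default_factory=list)

    @classmethod
    def empty(cls, N: int) -> "Population":
        return cls(
            geno=np.zeros((2 * N, 0), dtype=np.uint8),
            positions=np.empty(0),
            mclasses=np.empty(0, dtype=np.int8),
            sel=np.empty(0),
            ids=np.empty(0, dtype=np.int64),
            births=np.empty(0, dtype=np.int64),
        )

    @property
    def n_chrom(self) -> int:
        return self.geno.shape[0]

    @property
    def n_mut(self) -> int:
        return self.geno.shape[1]

    def counts(self) -> np.ndarray:
        return self.geno.sum(axis=0, dtype=np.int64)

    def copy(self) -> "Population":
        return Population(
            geno=self.geno.copy(),
            positions=self.positions.copy(),
            mclasses=self.mclasses.copy(),
            sel=self.sel.copy(),
            ids=self.ids.copy(),
            births=self.births.copy(),
            generation=self.generation,
            next_id=self.next_id,
            fixed=list(self.fixed),
        )


@dataclass
class SampleResult:
    """Per-class site frequency spectrum of a sample of ``n`` chromosomes.

    ``sfs_by_class[c][i-1]`` is the number of class-``c`` sites at derived
    count ``i`` in the sample, i = 1..n-1.  Sites fixed in the sample are not
    polymorphisms and are excluded.
    """

    sfs_by_class: dict[int, np.ndarray]
    n: int
    sweep_fixed: bool = False
    rep_id: int = 0
    epoch: int = 0


def individual_fitness(pop: Population, p: SimParams) -> np.ndarray:
    """Multiplicative fitness of each of the N diploids."""
    N = pop.n_chrom // 2
    selected = np.flatnonzero(pop.sel != 0.0)
    if selected.size == 0:
        return np.ones(N)
    ga = pop.geno[0::2][:, selected]
    gb = pop.geno[1::2][:, selected]
    g = ga.astype(np.int8) + gb
    s = pop.sel[selected]
    # lethal genotypes (1 + s <= 0) are zeroed explicitly rather than
    # letting -inf propagate through the matmul as 0 * inf = NaN
    lethal_het = (1.0 + p.h * s) <= 0
    lethal_hom = (1.0 + s) <= 0
    log_het = np.log(np.where(lethal_het, 1.0, 1.0 + p.h * s))
    log_hom = np.log(np.where(lethal_hom, 1.0, 1.0 + s))
    het = g == 1
    hom = g == 2
    w = np.exp(het @ log_het + hom @ log_hom)
    if lethal_het.any() or lethal_hom.any():
        dead = (het @ lethal_het.astype(float) + hom @ lethal_hom.astype(float)) > 0
        w[dead] = 0.0
    return w


def step_generation(pop: Population, p: SimParams, rng: np.random.Generator,
                    include_advantageous: bool = False) -> Population:
    """One Wright-Fisher generation: selection, transmission, recombination,
    mutation, and fixation bookkeeping.  Returns a new Population."""
    N = p.N
    two_n = 2 * N

    # -- selection: parent individual of each offspring chromosome
    w = individual_fitness(pop, p)
    w_tot = w.sum()
    if not np.isfinite(w_tot) or w_tot <= 0:
        raise DegenerateParametersError(
            "all individuals have fitness <= 0; selection parameters degenerate")
    parent = rng.choice(N, size=two_n, p=w / w_tot)
    strand = rng.integers(0, 2, size=two_n)

    # -- transmission: by default each gamete copies one parental chromosome
    geno = pop.geno[2 * parent + strand]

    # -- recombination: Poisson(rho) crossover events population-wide,
    #    each on a uniformly chosen gamete at a uniform breakpoint
    if p.rho > 0:
        k_events = rng.poisson(p.rho)
        if k_events and pop.n_mut > 0:
            targets = rng.integers(0, two_n, size=k_events)
            points = rng.random(k_events)
            for j in np.unique(targets):
                bps = np.sort(points[targets == j])
                # parity of breakpoints left of each site: even -> chosen
                # strand, odd -> the homologous chromosome
                parity = np.searchsorted(bps, pop.positions, side="right") % 2
                pa = pop.geno[2 * parent[j] + strand[j]]
                pb = pop.geno[2 * parent[j] + 1 - strand[j]]
                geno[j] = np.where(parity == 0, pa, pb)

    pop2 = Population(
        geno=np.ascontiguousarray(geno),
        positions=pop.positions.copy(),
        mclasses=pop.mclasses.copy(),
        sel=pop.sel.copy(),
        ids=pop.ids.copy(),
        births=pop.births.copy(),
        generation=pop.generation + 1,
        next_id=pop.next_id,
        fixed=pop.fixed,
    )

    # -- mutation: Poisson(2N u_x) new sites per class, u_x = theta_x / 4N
    rates = [(NEUTRAL, p.theta_n / 2.0, 0.0), (DELETERIOUS, p.theta_d / 2.0, p.s_d)]
    if include_advantageous:
        rates.append((ADVANTAGEOUS, p.theta_a / 2.0, p.s_a))
    for mclass, lam, s in rates:
        if lam <= 0:
            continue
        n_new = rng.poisson(lam)
        if n_new == 0:
            continue
        newpos = rng.random(n_new)
        # infinite sites: redraw on (vanishingly unlikely) position collision
        while np.isin(newpos, pop2.positions).any() or len(np.unique(newpos)) < n_new:
            newpos = rng.random(n_new)
        carriers = rng.integers(0, two_n, size=n_new)
        add = np.zeros((two_n, n_new), dtype=np.uint8)
        add[carriers, np.arange(n_new)] = 1
        pop2.geno = np.concatenate([pop2.geno, add], axis=1)
        pop2.positions = np.concatenate([pop2.positions, newpos])
        pop2.mclasses = np.concatenate([pop2.mclasses, np.full(n_new, mclass, dtype=np.int8)])
        pop2.sel = np.concatenate([pop2.sel, np.full(n_new, s)])
        pop2.ids = np.concatenate(
            [pop2.ids, np.arange(pop2.next_id, pop2.next_id + n_new, dtype=np.int64)])
        pop2.births = np.concatenate(
            [pop2.births, np.full(n_new, pop2.generation, dtype=np.int64)])
        pop2.next_id += n_new

    # -- strip lost and fixed mutations
    counts = pop2.counts()
    fixed_mask = counts == two_n
    if fixed_mask.any():
        for i in np.flatnonzero(fixed_mask):
            pop2.fixed.append(FixedMutation(
                id=int(pop2.ids[i]), position=float(pop2.positions[i]),
                mclass=int(pop2.mclasses[i]), birth_gen=int(pop2.births[i]),
                fixed_gen=pop2.generation))
    keep = (counts > 0) & ~fixed_mask
    if not keep.all():
        pop2.geno = np.ascontiguousarray(pop2.geno[:, keep])
        pop2.positions = pop2.positions[keep]
        pop2.mclasses = pop2.mclasses[keep]
        pop2.sel = pop2.sel[keep]
        pop2.ids = pop2.ids[keep]
        pop2.births = pop2.births[keep]
    return pop2


def burn_in(pop: Population, p: SimParams, rng: np.random.Generator,
            include_advantageous: bool = False,
            trajectory_every: int = 100) -> tuple[Population, list[dict]]:
    """Run 20N generations (or ``p.burn_in``) from the given population.

    Returns the equilibrated population and a per-class segregating-site
    trajectory logged every ``trajectory_every`` generations.
    """
    trajectory: list[dict] = []
    for g in range(p.n_burn_in):
        pop = step_generation(pop, p, rng, include_advantageous=include_advantageous)
        if trajectory_every and (g + 1) % trajectory_every == 0:
            trajectory.append({
                "generation": pop.generation,
                "S_neutral": int(np.sum(pop.mclasses == NEUTRAL)),
                "S_deleterious": int(np.sum(pop.mclasses == DELETERIOUS)),
                "S_advantageous": int(np.sum(pop.mclasses == ADVANTAGEOUS)),
            })
    return pop, trajectory


def sample_population(pop: Population, sample_n: int, rng: np.random.Generator,
                      sweep_fixed: bool = False, rep_id: int = 0,
                      epoch: int = 0, born_before: int | None = None) -> SampleResult:
    """SFS of ``sample_n`` chromosomes drawn without replacement.

    Counts 0 and n are excluded: sites absent from or fixed in the sample are
    not sample polymorphisms.  ``born_before`` restricts the spectrum to
    mutations that arose before that generation (e.g. pre-sweep standing
    variation).
    """
    idx = rng.choice(pop.n_chrom, size=sample_n, replace=False)
    counts = pop.geno[idx].sum(axis=0, dtype=np.int64)
    keep_birth = (pop.births < born_before if born_before is not None
                  else np.ones(pop.n_mut, dtype=bool))
    sfs_by_class = {}
    for mclass in (NEUTRAL, DELETERIOUS, ADVANTAGEOUS):
        sel = counts[(pop.mclasses == mclass) & keep_birth]
        sel = sel[(sel > 0) & (sel < sample_n)]
        sfs_by_class[mclass] = np.bincount(sel, minlength=sample_n)[1:sample_n]
    return SampleResult(sfs_by_class=sfs_by_class, n=sample_n,
                        sweep_fixed=sweep_fixed, rep_id=rep_id, epoch=epoch)


def _inject_sweep(pop: Population, p: SimParams) -> tuple[Population, int]:
    """Add one advantageous mutation at position 0.5 on chromosome 0's copy."""
    pop = pop.copy()
    two_n = pop.n_chrom
    add = np.zeros((two_n, 1), dtype=np.uint8)
    add[0, 0] = 1
    sweep_id = pop.next_id
    pop.geno = np.concatenate([pop.geno, add], axis=1)
    pop.positions = np.concatenate([pop.positions, [0.5]])
    pop.mclasses = np.concatenate([pop.mclasses, np.array([ADVANTAGEOUS], dtype=np.int8)])
    pop.sel = np.concatenate([pop.sel, [p.s_a]])
    pop.ids = np.concatenate([pop.ids, [sweep_id]])
    pop.births = np.concatenate([pop.births, [pop.generation]])
    pop.next_id += 1
    return pop, sweep_id


def run_single_sweep(p: SimParams, rng: np.random.Generator, rep_id: int = 0,
                     standing_sample: bool = False):
    """One hitchhiking event conditional on fixation.

    After burn-in a single advantageous mutation (selection ``s_a``) is
    injected at the chromosome centre at count 1.  If it is lost the exact
    pre-injection state is restored and a fresh attempt is made, so the
    returned sample is conditioned on fixation.  Returns
    ``(pre_sweep_sample, post_sweep_sample)`` drawn from the snapshot and the
    fixation generation respectively; with ``standing_sample`` a third
    SampleResult restricted to standing variation (mutations that predate
    the injection) is appended.
    """
    if p.gamma_a <= 0:
        raise ValueError("single-sweep mode requires gamma_a > 0")
    pop0 = Population.empty(p.N)
    pop0, _ = burn_in(pop0, p, rng)
    pre_sample = sample_population(pop0, p.sample_n, rng, rep_id=rep_id)
    inject_gen = pop0.generation

    for _ in range(p.max_sweep_attempts):
        pop, sweep_id = _inject_sweep(pop0, p)
        while True:
            prev_n_fixed = len(pop.fixed)
            pop = step_generation(pop, p, rng)
            if sweep_id in (f.id for f in pop.fixed[prev_n_fixed:]):
                post = sample_population(pop, p.sample_n, rng,
                                         sweep_fixed=True, rep_id=rep_id)
                if not standing_sample:
                    return pre_sample, post
                standing = sample_population(
                    pop, p.sample_n, rng, sweep_fixed=True, rep_id=rep_id,
                    born_before=inject_gen)
                return pre_sample, post, standing
            if not np.isin(sweep_id, pop.ids):
                break  # lost: snapshot pop0 is untouched, retry from it
    raise SweepAttemptsExceededError(
        f"sweep failed to fix within {p.max_sweep_attempts} attempts")


def run_recurrent_sweeps(p: SimParams, rng: np.random.Generator, n_epochs: int,
                         rep_id: int = 0) -> list[SampleResult]:
    """Recurrent hitchhiking: constant influx of advantageous mutations.

    Burn-in runs without the advantageous influx; afterwards advantageous
    mutations arise uniformly along the chromosome as part of each
    generation, and a sample is drawn every N generations for ``n_epochs``
    epochs (regardless of whether a sweep is in progress at sampling time).
    """
    pop = Population.empty(p.N)
    pop, _ = burn_in(pop, p, rng)
    results = []
    for epoch in range(1, n_epochs + 1):
        for _ in range(p.N):
            pop = step_generation(pop, p, rng, include_advantageous=True)
        results.append(sample_population(pop, p.sample_n, rng,
                                         rep_id=rep_id, epoch=epoch))
    return results
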