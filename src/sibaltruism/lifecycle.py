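"""Family-structured, non-overlapping-generations lifecycle.

One generation cycle:

1. every adult is paired with another adult uniformly at random (an odd
   leftover neither reproduces nor survives);
2. each pair produces a litter of four full siblings, each offspring formed
   from one recombinant gamete per parent;
3. within each litter one sibling pair is chosen uniformly at random to
   interact socially: an altruist (carrier of the dominant allele) pays a
   survival cost ``c`` and grants its partner a survival benefit ``b``; the
   two bystander siblings are unaffected;
4. density-dependent viability regulation: each juvenile survives with
   probability ``clamp(min(1, K/N_juv) * (w_del + delta_social), 0, 1)``
   where ``w_del`` is its multiplicative deleterious-mutation fitness and
   ``delta_social = b·[partner altruist] − c·[self altruist]`` for the two
   interacting siblings; survivors mature into adults and all parents die.

With carrying capacity ``K = 1000`` this yields roughly 1000 parents and
2000 offspring each generation, so a single allele copy inserted while both
cohorts are alive starts at frequency 1/6000.

The engine stores a population as a flat list of haplotype position arrays
(two per individual) plus a boolean altruism-flag array, and vectorises each
phase over the whole cohort; per-individual wrappers mirroring the phase
operations are provided for unit-level use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import compress
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genetics import (
    EMPTY_POSITIONS,
    GenomeParams,
    Haplotype,
    Individual,
    deleterious_fitness,
    make_gamete,
    recombine_and_mutate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LifecycleParams",
    "ReplicateOutcome",
    "ExtinctionError",
    "Population",
    "Juveniles",
    "pair_adults",
    "reproduce_litter",
    "reproduce",
    "assign_social_pair",
    "social_adjustment",
    "insert_altruistic_allele",
    "viability_and_regulation",
    "step",
    "burn_in",
    "run_replicate",
]


class ExtinctionError(RuntimeError):
    """Raised when a population drops below two adults (or to zero juveniles)."""


@dataclass(frozen=True)
class LifecycleParams:
    """Demographic and social parameters.

    ``social_mode`` selects how the cost/benefit act on the density-scaled
    survival probability: ``"additive"`` (default) adds ``b·[partner
    altruist] − c·[self altruist]``; ``"multiplicative"`` applies factors
    ``(1 − c)`` and ``(1 + b)`` instead.
    """

    K: int = 1000
    litter_size: int = 4
    c: float = 0.1
    b: float = 0.0
    burn_in_gens: int = 5000
    max_gens: Optional[int] = None  # default 40·K, i.e. 20 × (2K) generations
    social_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.litter_size < 2:
            raise ValueError(f"litter_size must be >= 2, got {self.litter_size}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if self.b < 0.0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.social_mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown social_mode {self.social_mode!r}")

    @property
    def absorption_limit(self) -> int:
        return self.max_gens if self.max_gens is not None else 40 * self.K


@dataclass(frozen=True)
class ReplicateOutcome:
    """Fate of one inserted allele copy."""

    fixed: bool
    generations: int
    replicate_seed: int
    censored: bool = False
    p0: float = 0.0  # realized initial frequency at insertion


@dataclass
class Population:
    """Adult population between generation cycles.

    ``haps[2*i]`` and ``haps[2*i + 1]`` are the two haplotypes of individual
    ``i`` (sorted int64 position arrays, treated as immutable and shared
    copy-on-write); ``alt`` is the matching altruism-flag array.
    """

    genome: GenomeParams
    haps: list[np.ndarray]
    alt: np.ndarray
    rng: np.random.Generator
    generation: int = 0

    @property
    def n(self) -> int:
        return len(self.haps) // 2

    @property
    def allele_count(self) -> int:
        return int(self.alt.sum())

    @classmethod
    def founders(cls, genome: GenomeParams, n: int, rng: np.random.Generator) -> "Population":
        """n mutation-free adults (the pre-burn-in founding state)."""
        return cls(
            genome=genome,
            haps=[EMPTY_POSITIONS] * (2 * n),
            alt=np.zeros(2 * n, dtype=bool),
            rng=rng,
        )

    @classmethod
    def from_individuals(
        cls, individuals: Sequence[Individual], genome: GenomeParams,
        rng: Optional[np.random.Generator] = None,
    ) -> "Population":
        haps: list[np.ndarray] = []
        alt: list[bool] = []
        for ind in individuals:
            haps.extend([ind.hap_a.positions, ind.hap_b.positions])
            alt.extend([ind.hap_a.has_altruism, ind.hap_b.has_altruism])
        return cls(
            genome=genome,
            haps=haps,
            alt=np.asarray(alt, dtype=bool),
            rng=rng if rng is not None else np.random.default_rng(),
        )

    def individual(self, i: int, stage: str = "adult") -> Individual:
        return Individual(
            hap_a=Haplotype(self.haps[2 * i], bool(self.alt[2 * i])),
            hap_b=Haplotype(self.haps[2 * i + 1], bool(self.alt[2 * i + 1])),
            stage=stage,
        )

    def to_individuals(self) -> list[Individual]:
        return [self.individual(i) for i in range(self.n)]

    def copy(self, rng: Optional[np.random.Generator] = None) -> "Population":
        """Cheap copy: haplotype arrays are shared (copy-on-write)."""
        return Population(
            genome=self.genome,
            haps=list(self.haps),
            alt=self.alt.copy(),
            rng=rng if rng is not None else self.rng,
            generation=self.generation,
        )

    # -- snapshot serialization (versioned JSON schema) -------------------

    def to_snapshot(self) -> dict:
        return {
            "format": "sibaltruism-snapshot",
            "version": 1,
            "generation": self.generation,
            "genome": {
                "L": self.genome.L,
                "rho": self.genome.rho,
                "u_del": self.genome.u_del,
                "s_del": self.genome.s_del,
                "h_del": self.genome.h_del,
                "altruism_pos": self.genome.altruism_pos,
            },
            "n_individuals": self.n,
            "haplotypes": [h.tolist() for h in self.haps],
            "altruism": np.flatnonzero(self.alt).tolist(),
            "rng_state": self.rng.bit_generator.state,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_snapshot()))

    @classmethod
    def from_snapshot(cls, snap: dict) -> "Population":
        if snap.get("format") != "sibaltruism-snapshot":
            raise ValueError("not a sibaltruism snapshot")
        genome = GenomeParams(**snap["genome"])
        haps = [np.asarray(h, dtype=np.int64) for h in snap["haplotypes"]]
        alt = np.zeros(len(haps), dtype=bool)
        alt[snap["altruism"]] = True
        rng = np.random.default_rng()
        rng.bit_generator.state = snap["rng_state"]
        return cls(genome=genome, haps=haps, alt=alt, rng=rng,
                   generation=snap["generation"])

    @classmethod
    def load(cls, path: str | Path) -> "Population":
        return cls.from_snapshot(json.loads(Path(path).read_text()))


@dataclass
class Juveniles:
    """Transient offspring cohort within one cycle.

    ``src[g]`` is the index of the parental chromosome that provided the
    focal-locus (bp 1000) copy of gamete ``g`` — the hook used to measure the
    variance in reproductive success.
    """

    haps: list[np.ndarray]
    alt: np.ndarray
    src: np.ndarray
    n: int


# ---------------------------------------------------------------------------
# lifecycle phases
# ---------------------------------------------------------------------------

def pair_adults(pop: Population, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random perfect matching on adults.

    Returns (mothers, fathers) index arrays of equal length N//2; with an odd
    adult count exactly one adult is left out (it neither reproduces nor
    survives).  Raises :class:`ExtinctionError` below two adults.
    """
    n = pop.n
    if n < 2:
        raise ExtinctionError(f"only {n} adult(s) left at generation {pop.generation}")
    perm = rng.permutation(n)
    npairs = n // 2
    return perm[:npairs], perm[npairs : 2 * npairs]


def reproduce(
    pop: Population,
    mothers: np.ndarray,
    fathers: np.ndarray,
    life: LifecycleParams,
    rng: np.random.Generator,
) -> Juveniles:
    """Produce a litter of ``litter_size`` full siblings per pair.

    Gametes are batched: crossover and mutation counts are drawn for the
    whole cohort at once and only the (rare) gametes with at least one event
    take the full recombination path.
    """
    genome = pop.genome
    ls = life.litter_size
    n_litters = mothers.size
    n_juv = ls * n_litters
    n_gam = 2 * n_juv

    par = np.empty(n_gam, dtype=np.int64)
    par[0::2] = np.repeat(mothers, ls)
    par[1::2] = np.repeat(fathers, ls)

    start = rng.integers(0, 2, size=n_gam)
    xo_mean = genome.expected_crossovers
    mut_mean = genome.u_del * genome.L
    k = rng.poisson(xo_mean, size=n_gam) if xo_mean > 0 else np.zeros(n_gam, np.int64)
    m = rng.poisson(mut_mean, size=n_gam) if mut_mean > 0 else np.zeros(n_gam, np.int64)

    src = 2 * par + start
    haps = [pop.haps[i] for i in src]
    alt = pop.alt[src]

    special = np.flatnonzero((k > 0) | (m > 0))
    if special.size:
        ks = k[special]
        ms = m[special]
        all_bps = rng.integers(2, genome.L + 1, size=int(ks.sum()))
        all_mut = rng.integers(1, genome.L, size=int(ms.sum()))
        all_mut[all_mut >= genome.altruism_pos] += 1
        off_b = np.concatenate(([0], np.cumsum(ks)))
        off_m = np.concatenate(([0], np.cumsum(ms)))
        pop_haps = pop.haps
        pop_alt = pop.alt
        for i in range(special.size):
            g = int(special[i])
            p = int(par[g])
            pos, _, side = recombine_and_mutate(
                pop_haps[2 * p], pop_haps[2 * p + 1],
                bool(pop_alt[2 * p]), bool(pop_alt[2 * p + 1]),
                int(start[g]),
                all_bps[off_b[i] : off_b[i + 1]],
                all_mut[off_m[i] : off_m[i + 1]],
                genome,
            )
            haps[g] = pos
            src[g] = 2 * p + side
            alt[g] = pop_alt[src[g]]

    return Juveniles(haps=haps, alt=alt, src=src, n=n_juv)


def reproduce_litter(
    mother: Individual,
    father: Individual,
    genome: GenomeParams,
    life: LifecycleParams,
    rng: np.random.Generator,
    litter_id: int = 0,
) -> list[Individual]:
    """Per-pair wrapper: four juveniles, one gamete from each parent."""
    if mother is father:
        raise ValueError("self-pairing is not allowed")
    juveniles = []
    for _ in range(life.litter_size):
        juveniles.append(
            Individual(
                hap_a=make_gamete(mother, genome, rng),
                hap_b=make_gamete(father, genome, rng),
                stage="juvenile",
                litter_id=litter_id,
            )
        )
    return juveniles


def _social_pair_indices(
    n_litters: int, litter_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Within-litter offsets of the interacting pair, uniform over all pairs."""
    a = rng.integers(0, litter_size, size=n_litters)
    off = rng.integers(1, litter_size, size=n_litters)
    b = (a + off) % litter_size
    return a, b


def assign_social_pair(
    litter: Sequence[Individual], rng: np.random.Generator
) -> tuple[int, int]:
    """Choose the interacting sibling pair, each of the C(n,2) pairs equally
    likely; flags the two on the Individual records and returns their indices."""
    n = len(litter)
    a, b = _social_pair_indices(1, n, rng)
    i, j = int(a[0]), int(b[0])
    litter[i].social_partner = j
    litter[j].social_partner = i
    return (i, j) if i < j else (j, i)


def social_adjustment(ind: Individual, partner: Individual, life: LifecycleParams) -> float:
    """Additive survival delta for one member of the interacting pair:
    ``b·[partner is altruist] − c·[self is altruist]``; bystanders get 0."""
    from .genetics import altruism_phenotype

    return life.b * altruism_phenotype(partner) - life.c * altruism_phenotype(ind)


def insert_altruistic_allele(
    pop: Population, juveniles: Juveniles, rng: np.random.Generator
) -> float:
    """Insert one allele copy into a uniformly chosen chromosome.

    The population momentarily holds parents plus the whole offspring cohort,
    so every one of the ``2·(N_parents + N_juv)`` chromosomes is eligible
    (a copy landing on a parent chromosome dies with the parent).  Returns the
    realized initial frequency.  Raises if the allele is already present.
    """
    if pop.alt.any() or juveniles.alt.any():
        raise ValueError("altruism allele already present at insertion")
    total = pop.alt.size + juveniles.alt.size
    i = int(rng.integers(total))
    if i < pop.alt.size:
        pop.alt[i] = True
    else:
        juveniles.alt[i - pop.alt.size] = True
    return 1.0 / total


def _cohort_fitness(juv: Juveniles, genome: GenomeParams) -> Optional[np.ndarray]:
    """Vectorised multiplicative deleterious fitness for the whole cohort.

    Returns None when every juvenile has fitness exactly 1.
    """
    if genome.s_del == 0.0:
        return None
    lens = np.fromiter((h.size for h in juv.haps), dtype=np.int64, count=2 * juv.n)
    if lens.sum() == 0:
        return None
    pos = np.concatenate(juv.haps)
    gam = np.repeat(np.arange(2 * juv.n), lens)
    side_a = (gam & 1) == 0
    key = (gam >> 1) * np.int64(genome.L + 1) + pos
    uniq, inv, tot = np.unique(key, return_inverse=True, return_counts=True)
    ca = np.bincount(inv, weights=side_a, minlength=uniq.size)
    hom = np.minimum(ca, tot - ca)
    het = tot - 2 * hom
    jk = uniq // np.int64(genome.L + 1)
    n_hom = np.bincount(jk, weights=hom, minlength=juv.n)
    n_het = np.bincount(jk, weights=het, minlength=juv.n)
    return (1.0 + genome.h_del * genome.s_del) ** n_het * (1.0 + genome.s_del) ** n_hom


def _substitute_fixed(pop: Population) -> None:
    """Remove one copy of every position present on all chromosomes.

    With multiplicative fitness this rescales every individual equally;
    it keeps the position arrays bounded over long runs.
    """
    haps = pop.haps
    if len(haps) < 2:
        return
    inter = np.intersect1d(haps[0], haps[1])
    for h in haps[2:]:
        if inter.size == 0:
            return
        inter = inter[np.isin(inter, h)]
    if inter.size == 0:
        return
    new = []
    for h in haps:
        idx = np.searchsorted(h, inter, side="left")
        keep = np.ones(h.size, dtype=bool)
        keep[idx] = False
        new.append(h[keep])
    pop.haps = new


def viability_and_regulation(
    pop: Population,
    juv: Juveniles,
    life: LifecycleParams,
    rng: np.random.Generator,
    social_a: np.ndarray,
    social_b: np.ndarray,
    track: bool = False,
) -> Optional[np.ndarray]:
    """Density-regulated juvenile survival; parents die; survivors mature.

    Survival probability of juvenile j is
    ``clamp(min(1, K/N_juv) · (w_del(j) + delta_social(j)), 0, 1)`` (additive
    mode: the social delta acts on the fitness scale, baseline 1, so the
    relative survival effect of a cost c is exactly −c) or
    ``clamp(min(1, K/N_juv) · w_del(j) · (1−c·self)(1+b·partner), 0, 1)``
    (multiplicative mode).  Updates ``pop`` in place and increments the
    generation counter.  When ``track`` is set, returns the per-parental-
    chromosome counts of focal-locus copies surviving into the next
    generation (non-transmitting chromosomes count 0).
    """
    n_juv = juv.n
    if n_juv == 0:
        raise ExtinctionError(f"no juveniles at generation {pop.generation}")
    n_parent_chrom = len(pop.haps)
    dens = min(1.0, life.K / n_juv)
    fit = _cohort_fitness(juv, pop.genome)

    pheno = juv.alt[0::2] | juv.alt[1::2]
    ls = life.litter_size
    base = ls * np.arange(social_a.size)
    i1 = base + social_a
    i2 = base + social_b
    p = np.full(n_juv, dens) if fit is None else dens * fit
    if life.social_mode == "additive":
        delta = np.zeros(n_juv)
        delta[i1] = life.b * pheno[i2] - life.c * pheno[i1]
        delta[i2] = life.b * pheno[i1] - life.c * pheno[i2]
        p += dens * delta
    else:
        factor = np.ones(n_juv)
        factor[i1] = (1.0 - life.c * pheno[i1]) * (1.0 + life.b * pheno[i2])
        factor[i2] = (1.0 - life.c * pheno[i2]) * (1.0 + life.b * pheno[i1])
        p *= factor
    np.clip(p, 0.0, 1.0, out=p)

    survive = rng.random(n_juv) < p
    if not survive.any():
        raise ExtinctionError(f"all juveniles died at generation {pop.generation}")
    gam_keep = np.repeat(survive, 2)
    pop.haps = list(compress(juv.haps, gam_keep))
    pop.alt = juv.alt[gam_keep]
    pop.generation += 1
    if pop.genome.u_del > 0:
        # fixed sites with s != 0 depress everyone's survival until removed,
        # so substitute promptly; fixed neutral sites have no fitness effect
        # and are swept only periodically (memory management)
        if pop.genome.s_del != 0.0 or pop.generation % 25 == 0:
            _substitute_fixed(pop)
    if track:
        return np.bincount(juv.src[gam_keep], minlength=n_parent_chrom)
    return None


def step(
    pop: Population,
    life: LifecycleParams,
    *,
    insert: bool = False,
    track: bool = False,
) -> tuple[Optional[np.ndarray], float]:
    """Run one full generation cycle in place.

    Returns ``(transmitted_counts_or_None, p0)`` where ``p0`` is the realized
    insertion frequency (0.0 unless ``insert``).
    """
    rng = pop.rng
    mothers, fathers = pair_adults(pop, rng)
    juv = reproduce(pop, mothers, fathers, life, rng)
    p0 = insert_altruistic_allele(pop, juv, rng) if insert else 0.0
    a, b = _social_pair_indices(mothers.size, life.litter_size, rng)
    counts = viability_and_regulation(pop, juv, life, rng, a, b, track=track)
    return counts, p0


def burn_in(
    genome: GenomeParams,
    life: LifecycleParams,
    seed: int | np.random.SeedSequence,
    record_pi_every: int = 100,
) -> tuple[Population, list[tuple[int, float]]]:
    """Generate a seed population at mutation–selection balance.

    Runs ``life.burn_in_gens`` full cycles without the altruism allele,
    starting from ``K`` mutation-free founders, and records the nucleotide
    diversity trajectory every ``record_pi_every`` generations (plus the
    final state).  Returns ``(population, pi_trace)``.
    """
    from .stats import pi_from_haplotypes  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    pop = Population.founders(genome, life.K, rng)
    trace: list[tuple[int, float]] = []
    for g in range(life.burn_in_gens):
        if record_pi_every and g % record_pi_every == 0:
            trace.append((pop.generation, pi_from_haplotypes(pop.haps, genome.L)))
            logger.debug(
                "burn-in gen %d: N=%d, pi=%.3e", pop.generation, pop.n, trace[-1][1]
            )
        step(pop, life)
    trace.append((pop.generation, pi_from_haplotypes(pop.haps, genome.L)))
    return pop, trace


def run_replicate(
    seed_pop: Population,
    life: LifecycleParams,
    replicate_seed: int | np.random.SeedSequence,
) -> ReplicateOutcome:
    """Insert one allele copy into a copy of ``seed_pop`` and run to absorption.

    Deterministic given (snapshot, replicate_seed).  The replicate ends when
    the allele count reaches 0 (lost) or every chromosome carries it (fixed);
    hitting ``life.absorption_limit`` generations is reported as censored,
    never silently as loss.  Population extinction (possible only at tiny K)
    removes every copy and is recorded as loss.
    """
    if isinstance(replicate_seed, np.random.SeedSequence):
        seed_int = int(replicate_seed.generate_state(1)[0])
        rng = np.random.default_rng(replicate_seed)
    else:
        seed_int = int(replicate_seed)
        rng = np.random.default_rng(seed_int)
    pop = seed_pop.copy(rng=rng)
    limit = life.absorption_limit
    gens = 0
    try:
        _, p0 = step(pop, life, insert=True)
        gens = 1
        while True:
            count = pop.allele_count
            if count == 0:
                return ReplicateOutcome(False, gens, seed_int, p0=p0)
            if count == pop.alt.size:
                return ReplicateOutcome(True, gens, seed_int, p0=p0)
            if gens >= limit:
                return ReplicateOutcome(False, gens, seed_int, censored=True, p0=p0)
            step(pop, life)
            gens += 1
    except ExtinctionError:
        return ReplicateOutcome(False, gens, seed_int, p0=0.0)
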