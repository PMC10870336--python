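"""Genome representation, gamete formation, and fitness from deleterious mutations.

A diploid individual carries two haplotypes of a contiguous genomic region of
length ``L`` base pairs.  Each haplotype is represented sparsely as a sorted
integer array of positions carrying deleterious mutations, plus a boolean flag
for the focal altruism allele, which sits at a fixed position
(``altruism_pos``, bp 1000 by default) and is never created by mutation.

Deleterious mutations arise at rate ``u_del`` per bp per gamete, all with the
same selection coefficient ``s_del`` and dominance ``h_del``; fitness is
multiplicative across sites.  Crossovers occur at rate ``rho`` per bp per
gamete.  Mutation "stacking" is allowed: the position arrays are multisets,
and two copies at the same position on one haplotype each contribute a
fitness factor (collisions are vanishingly rare at the default rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GenomeParams",
    "Haplotype",
    "Individual",
    "EMPTY_POSITIONS",
    "make_gamete",
    "deleterious_fitness",
    "altruism_phenotype",
    "site_counts",
]

#: Shared immutable empty position array (haplotypes are copy-on-write).
EMPTY_POSITIONS = np.empty(0, dtype=np.int64)
EMPTY_POSITIONS.setflags(write=False)


@dataclass(frozen=True)
class GenomeParams:
    """Static genomic parameters of a scenario.

    Coordinates are 1-based on the closed interval ``[1, L]``.  The expected
    crossover count per gamete uses the per-interval map length
    ``rho * (L - 1)``; the difference from ``rho * L`` is negligible at the
    default rates.
    """

    L: int = 100_000
    rho: float = 1e-8
    u_del: float = 5e-8
    s_del: float = 0.0
    h_del: float = 0.5
    altruism_pos: int = 1000

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.u_del < 0:
            raise ValueError(f"u_del must be >= 0, got {self.u_del}")
        if not -1.0 <= self.s_del <= 0.0:
            raise ValueError(f"s_del must lie in [-1, 0], got {self.s_del}")
        if not 0.0 <= self.h_del <= 1.0:
            raise ValueError(f"h_del must lie in [0, 1], got {self.h_del}")
        if not 1 <= self.altruism_pos <= self.L:
            raise ValueError(
                f"altruism_pos must lie in [1, L], got {self.altruism_pos}"
            )

    @property
    def U(self) -> float:
        """Total diploid deleterious mutation rate of the region, 2·u·L."""
        return 2.0 * self.u_del * self.L

    @property
    def R(self) -> float:
        """Map length of the region in Morgans, rho·L."""
        return self.rho * self.L

    @property
    def expected_crossovers(self) -> float:
        return self.rho * (self.L - 1)

    @property
    def expected_mutations(self) -> float:
        return self.u_del * self.L


@dataclass
class Haplotype:
    """One chromosome copy: deleterious positions plus the altruism flag."""

    positions: np.ndarray = field(default_factory=lambda: EMPTY_POSITIONS)
    has_altruism: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Haplotype):
            return NotImplemented
        return bool(
            self.has_altruism == other.has_altruism
            and self.positions.shape == other.positions.shape
            and np.array_equal(self.positions, other.positions)
        )


@dataclass
class Individual:
    """A diploid individual with family bookkeeping used by the lifecycle."""

    hap_a: Haplotype
    hap_b: Haplotype
    stage: str = "adult"  # "adult" | "juvenile"
    litter_id: Optional[int] = None
    social_partner: Optional[int] = None  # index of litter-mate it interacts with


def _draw_new_mutations(m: int, params: GenomeParams, rng: np.random.Generator) -> np.ndarray:
    """m new deleterious positions, uniform on [1, L] excluding the altruism locus."""
    pos = rng.integers(1, params.L, size=m)  # uniform on [1, L-1]
    pos[pos >= params.altruism_pos] += 1  # shift past the focal locus -> [1,L] \ {pos_alt}
    return pos


def recombine_and_mutate(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    alt_a: bool,
    alt_b: bool,
    start: int,
    breakpoints: np.ndarray,
    new_mut: np.ndarray,
    params: GenomeParams,
) -> tuple[np.ndarray, bool, int]:
    """Assemble one gamete from two parental haplotypes.

    ``start`` selects the haplotype providing position 1 (0 = a, 1 = b); a
    breakpoint at ``x`` switches the source for all positions >= x.  Returns
    the sorted position array (shared with the parent when nothing happened),
    the altruism flag inherited at ``altruism_pos``, and the index (0/1) of
    the haplotype that provided the focal locus.
    """
    haps = (pos_a, pos_b)
    alts = (alt_a, alt_b)
    if breakpoints.size == 0:
        if new_mut.size == 0:
            return haps[start], alts[start], start
        merged = np.concatenate((haps[start], new_mut))
        merged.sort()
        return merged, alts[start], start
    bps = breakpoints.copy()
    bps.sort()
    # a breakpoint at x switches the source for positions >= x, so the source
    # of position p is start XOR (number of breakpoints <= p) mod 2
    sel_a = ((start + bps.searchsorted(pos_a, side="right")) & 1) == 0
    sel_b = ((start + bps.searchsorted(pos_b, side="right")) & 1) == 1
    if new_mut.size:
        out = np.concatenate((pos_a[sel_a], pos_b[sel_b], new_mut))
    else:
        out = np.concatenate((pos_a[sel_a], pos_b[sel_b]))
    out.sort()
    side = (start + int(bps.searchsorted(params.altruism_pos, side="right"))) & 1
    return out, alts[side], side


def make_gamete(parent: Individual, params: GenomeParams, rng: np.random.Generator) -> Haplotype:
    """Form one gamete: recombine the parental haplotypes, then mutate.

    Crossover count is Poisson(rho·(L−1)) with breakpoints uniform on (1, L];
    the starting haplotype is chosen with probability 1/2.  New deleterious
    mutation count is Poisson(u_del·L), positions uniform on [1, L] excluding
    the altruism locus.
    """
    k = rng.poisson(params.expected_crossovers)
    m = rng.poisson(params.u_del * params.L)
    start = int(rng.integers(0, 2))
    bps = rng.integers(2, params.L + 1, size=k) if k else EMPTY_POSITIONS
    mut = _draw_new_mutations(m, params, rng) if m else EMPTY_POSITIONS
    pos, alt, _ = recombine_and_mutate(
        parent.hap_a.positions,
        parent.hap_b.positions,
        parent.hap_a.has_altruism,
        parent.hap_b.has_altruism,
        start,
        bps,
        mut,
        params,
    )
    return Haplotype(pos, alt)


def site_counts(pos_a: np.ndarray, pos_b: np.ndarray) -> tuple[int, int]:
    """(n_het, n_hom) factor counts over the two haplotype multisets.

    At each position, min(copies on a, copies on b) pairs count as homozygous
    factors and the remainder as heterozygous factors.
    """
    if pos_a.size == 0 and pos_b.size == 0:
        return 0, 0
    allpos = np.concatenate([pos_a, pos_b])
    uniq, tot = np.unique(allpos, return_counts=True)
    ca = np.searchsorted(pos_a, uniq, side="right") - np.searchsorted(pos_a, uniq, side="left")
    hom = np.minimum(ca, tot - ca)
    n_hom = int(hom.sum())
    n_het = int(tot.sum()) - 2 * n_hom
    return n_het, n_hom


def deleterious_fitness(ind: Individual, params: GenomeParams) -> float:
    """Multiplicative fitness over deleterious sites.

    Each heterozygous site contributes (1 + h_del·s_del), each homozygous site
    (1 + s_del).  With no mutations the fitness is exactly 1.
    """
    n_het, n_hom = site_counts(ind.hap_a.positions, ind.hap_b.positions)
    if n_het == 0 and n_hom == 0:
        return 1.0
    return (1.0 + params.h_del * params.s_del) ** n_het * (1.0 + params.s_del) ** n_hom


def altruism_phenotype(ind: Individual) -> bool:
    """True iff the individual carries the (completely dominant) altruism allele."""
    return bool(ind.hap_a.has_altruism or ind.hap_b.has_altruism)
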