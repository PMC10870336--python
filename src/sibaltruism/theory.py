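"""Analytic layer: diffusion fixation probability, effective sizes, Hamilton's rule.

The fixation probability of an allele with selection coefficient ``S`` and
dominance ``h`` starting at frequency ``p0`` in a diploid population of
effective size ``Ne`` is the classic diffusion ratio

    p_fix = integral_0^p0 psi(x) dx / integral_0^1 psi(x) dx,
    psi(x) = exp(-2 Ne S x (2h + x (1 - 2h))).

Background selection from recurrent deleterious mutations in a linked region
rescales the effective size.  For a focal locus at one end of a region with
total diploid deleterious mutation rate ``U``, map length ``R`` Morgans, and
deleterious effect/dominance ``s_del``/``h_del``, the Hudson–Kaplan
approximation gives

    Ne_bg = Ne * exp(-U / (2 |s_del h_del| + R)),

which reduces to the familiar no-recombination load result
``Ne exp(-U / (2 h s))`` as R -> 0.

For altruism between full siblings (relatedness r = 1/2) where one of the
two sibling pairs per litter interacts, the focal selection coefficient is
half the inclusive fitness effect: ``S = (-c + r b) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TheoryInputs",
    "fixation_probability_diffusion",
    "effective_size_from_variance",
    "ne_background_selection",
    "altruism_selection_coefficient",
    "hamilton_critical_benefit",
    "predicted_fixation_with_bgs",
]


@dataclass(frozen=True)
class TheoryInputs:
    """Bundle of quantities entering the analytic predictions.

    Defaults are the headline parameterization: census size N = 1000 with
    variance in reproductive success sigma2 = 0.75 (hence Ne ≈ 1333), a fully
    dominant focal allele inserted at frequency 1/6000, and a 100-kb region
    with U = 1e-2 and R = 1e-3.
    """

    N: float = 1000.0
    sigma2: float = 0.75
    S: float = 0.0
    h: float = 1.0
    p0: float = 1.0 / 6000.0
    U: float = 1e-2
    R: float = 1e-3
    s_del: float = 0.0
    h_del: float = 0.5
    r: float = 0.5

    @property
    def Ne(self) -> float:
        return effective_size_from_variance(self.N, self.sigma2)


def fixation_probability_diffusion(Ne: float, S: float, h: float, p0: float) -> float:
    """Diffusion fixation probability by adaptive quadrature.

    The integrand exponent is shifted by its maximum over [0, 1] (a log-sum-exp
    guard) so the ratio stays finite for large ``|2 Ne S|``; relative
    tolerance 1e-10 on each integral.
    """
    if not (np.isfinite(Ne) and np.isfinite(S) and np.isfinite(h) and np.isfinite(p0)):
        raise ValueError("non-finite diffusion parameters")
    if Ne <= 0:
        raise ValueError(f"Ne must be positive, got {Ne}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if S == 0.0:
        return p0  # psi == 1 exactly

    a = 2.0 * Ne * S

    def g(x: float) -> float:
        return -a * x * (2.0 * h + x * (1.0 - 2.0 * h))

    # exponent maximum over [0, 1]: endpoints or interior vertex
    cands = [0.0, 1.0]
    if h != 0.5:
        v = -h / (1.0 - 2.0 * h)
        if 0.0 < v < 1.0:
            cands.append(v)
    m = max(g(x) for x in cands)

    def psi(x: float) -> float:
        return math.exp(g(x) - m)

    num, _ = quad(psi, 0.0, p0, epsabs=0.0, epsrel=1e-10, limit=200)
    den, _ = quad(psi, 0.0, 1.0, epsabs=0.0, epsrel=1e-10, limit=200,
                  points=[p0] if 0.0 < p0 < 1.0 else None)
    if den == 0.0:
        raise ValueError("diffusion denominator underflowed")
    return float(min(max(num / den, 0.0), 1.0))


def effective_size_from_variance(N: float, sigma2: float) -> float:
    """Effective size accounting for variance in reproductive success: N / sigma2."""
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    return N / sigma2


def ne_background_selection(Ne: float, U: float, s_del: float, h_del: float, R: float) -> float:
    """Background-selection-adjusted effective size, Ne·exp(−U / (2|s_del·h_del| + R))."""
    if Ne <= 0:
        raise ValueError(f"Ne must be positive, got {Ne}")
    if U < 0 or R < 0:
        raise ValueError("U and R must be nonnegative")
    denom = 2.0 * abs(s_del * h_del) + R
    if denom == 0.0:
        if U == 0.0:
            return Ne
        raise ValueError("zero denominator: both s_del*h_del and R are 0 with U > 0")
    return Ne * math.exp(-U / denom)


def altruism_selection_coefficient(
    c: float, b: float, r: float = 0.5, interaction_fraction: float = 0.5
) -> float:
    """Selection coefficient of the altruism allele.

    The inclusive fitness effect is ``−c + r·b``; because only one of the two
    sibling pairs per litter interacts, half of it acts per generation:
    ``S = interaction_fraction · (−c + r·b)``.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relatedness r must lie in [0, 1], got {r}")
    return interaction_fraction * (-c + r * b)


def hamilton_critical_benefit(c: float, r: float = 0.5) -> float:
    """Benefit threshold from Hamilton's rule: the allele is favored iff b > c/r."""
    if r <= 0:
        raise ValueError(f"relatedness r must be positive, got {r}")
    return c / r


def predicted_fixation_with_bgs(
    c: float,
    b: float,
    s_del: float,
    *,
    r: float = 0.5,
    h: float = 1.0,
    h_del: float = 0.5,
    Ne: float = 1000.0 / 0.75,
    U: float = 1e-2,
    R: float = 1e-3,
    p0: float = 1.0 / 6000.0,
    interaction_fraction: float = 0.5,
) -> float:
    """Composite prediction: Ne → Ne_bg → diffusion fixation probability.

    ``s_del = 0`` means no linked deleterious mutations, so Ne is unchanged;
    for any other ``s_del`` the Hudson–Kaplan reduction is applied (at
    ``s_del = −1`` the reduction is negligible, ≈ 1%, matching the treatment
    of strongly deleterious mutations as effectively no background selection).
    """
    S = altruism_selection_coefficient(c, b, r, interaction_fraction)
    ne_eff = Ne if s_del == 0.0 else ne_background_selection(Ne, U, s_del, h_del, R)
    return fixation_probability_diffusion(ne_eff, S, h, p0)
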