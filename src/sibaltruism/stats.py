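"""Estimators and summaries: fixation estimates, diversity, sigma^2, regression.

Fixation probabilities are estimated as binomial fractions with exact
Clopper–Pearson confidence intervals (the estimated probabilities are of
order 1e-4, where normal approximations misbehave).  Nucleotide diversity pi
is the mean pairwise difference per site over all chromosomes with the
2N/(2N-1) small-sample correction.  The variance in reproductive success
sigma^2 is measured by tracking, for every chromosome, how many copies of
the neutral focal locus (bp 1000) survive into the next generation; under
the family lifecycle (litters of four, ~50% juvenile survival) each
chromosome transmits Binomial(4, 1/4) copies, hence sigma^2 ~ 0.75 versus 1
under Wright-Fisher resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .genetics import GenomeParams
from .lifecycle import LifecycleParams, Population, ReplicateOutcome, step

__all__ = [
    "FixationEstimate",
    "estimate_fixation",
    "clopper_pearson",
    "binomial_ci_for_prediction",
    "pi_from_haplotypes",
    "heterozygosity_pi",
    "variance_reproductive_success",
    "measure_reproductive_variance",
    "fixation_logistic_regression",
    "plot_pi_traces",
]


@dataclass(frozen=True)
class FixationEstimate:
    n_replicates: int
    n_fixed: int
    p_hat: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    n_censored: int = 0


def clopper_pearson(k: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval from beta quantiles; accepts fractional k
    (used for intervals around a predicted expected count)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def estimate_fixation(
    outcomes: Iterable[ReplicateOutcome], level: float = 0.95
) -> FixationEstimate:
    """Fixation fraction with an exact CI; censored replicates are excluded
    from the estimate and counted separately."""
    outcomes = list(outcomes)
    censored = sum(o.censored for o in outcomes)
    done = [o for o in outcomes if not o.censored]
    if not done:
        raise ValueError("all replicates censored; no estimate possible")
    n = len(done)
    k = sum(o.fixed for o in done)
    low, high = clopper_pearson(k, n, level)
    return FixationEstimate(
        n_replicates=n, n_fixed=k, p_hat=k / n,
        ci_low=low, ci_high=high, ci_level=level, n_censored=censored,
    )


def binomial_ci_for_prediction(p_pred: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% interval for the fixation fraction of n replicates if the true
    probability were ``p_pred`` (Clopper–Pearson at the expected count)."""
    if not 0.0 <= p_pred <= 1.0:
        raise ValueError("p_pred must lie in [0, 1]")
    return clopper_pearson(p_pred * n, n, level)


def pi_from_haplotypes(haps: Sequence[np.ndarray], L: int) -> float:
    """Mean pairwise diversity per site over a list of haplotype position arrays.

    pi = sum over segregating sites of 2 p (1-p) · 2N/(2N-1), divided by L,
    where p counts the fraction of chromosomes carrying the site (presence,
    ignoring stacked duplicates).
    """
    n_chrom = len(haps)
    if n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    nonempty = [np.unique(h) for h in haps if h.size]
    if not nonempty:
        return 0.0
    counts = np.unique(np.concatenate(nonempty), return_counts=True)[1]
    p = counts / n_chrom
    het = 2.0 * p * (1.0 - p) * (n_chrom / (n_chrom - 1.0))
    return float(het.sum() / L)


def heterozygosity_pi(pop: Population) -> float:
    """Diversity of a population's adult chromosomes (deleterious/neutral sites)."""
    return pi_from_haplotypes(pop.haps, pop.genome.L)


def variance_reproductive_success(counts: Iterable[np.ndarray] | np.ndarray) -> float:
    """Variance of transmitted-copy counts pooled across chromosomes and
    generations (sample variance)."""
    if isinstance(counts, np.ndarray):
        pooled = counts.ravel()
    else:
        pooled = np.concatenate([np.asarray(c).ravel() for c in counts])
    if pooled.size < 2:
        raise ValueError("need at least 2 transmitted-copy records")
    return float(np.var(pooled, ddof=1))


def measure_reproductive_variance(
    K: int = 1000,
    generations: int = 50,
    n_runs: int = 10,
    seed: int | np.random.SeedSequence = 0,
    discard: int = 10,
) -> tuple[float, int]:
    """Measure sigma^2 in the neutral lifecycle (no mutations, no social effects).

    Runs ``n_runs`` independently seeded populations for ``discard +
    generations`` cycles each, tracking per-chromosome transmitted copies of
    the focal locus over the last ``generations`` cycles.  Returns
    ``(sigma2, n_records)``.
    """
    genome = GenomeParams(u_del=0.0, s_del=0.0)
    life = LifecycleParams(K=K, c=0.0, b=0.0, burn_in_gens=0)
    base = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    records: list[np.ndarray] = []
    for child in base.spawn(n_runs):
        pop = Population.founders(genome, K, np.random.default_rng(child))
        for g in range(discard + generations):
            counts, _ = step(pop, life, track=g >= discard)
            if counts is not None:
                records.append(counts)
    pooled = np.concatenate(records)
    return float(np.var(pooled, ddof=1)), int(pooled.size)


def fixation_logistic_regression(table: pd.DataFrame) -> pd.DataFrame:
    """Fit ``fixed ~ benefit * bgs`` by maximum likelihood (IRLS).

    ``table`` needs columns ``benefit`` (float), ``bgs`` (0/1 flag: linked
    deleterious mutations in the weakly-selected range), and ``fixed``
    (0/1 outcome per replicate).  Returns a tidy frame with columns
    (term, estimate, std_error, z_value).  Complete separation is flagged:
    the affected coefficients are reported as non-finite rather than raising.
    """
    import statsmodels.api as sm

    for col in ("benefit", "bgs", "fixed"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["bgs"].nunique() < 2:
        raise ValueError("need both background-selection levels")
    if table["benefit"].nunique() < 2:
        raise ValueError("need at least 2 benefit values")

    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "Benefit": table["benefit"].astype(float),
            "BGS": table["bgs"].astype(float),
            "Benefit x BGS": table["benefit"].astype(float) * table["bgs"].astype(float),
        }
    )
    y = table["fixed"].astype(float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
        params, bse = res.params, res.bse
    except Exception:  # perfect separation or non-convergence
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
    out = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": params.to_numpy(),
            "std_error": bse.to_numpy(),
        }
    )
    out["z_value"] = out["estimate"] / out["std_error"]
    return out


def plot_pi_traces(trace: pd.DataFrame, ax=None):
    """Minimal convenience plot of diversity trajectories.

    ``trace`` needs columns (generation, pi) and optionally (s_del, seed_id);
    one line per (s_del, seed_id) group.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    group_cols = [c for c in ("s_del", "seed_id") if c in trace.columns]
    if group_cols:
        for key, grp in trace.groupby(group_cols):
            ax.plot(grp["generation"], grp["pi"], label=str(key), alpha=0.7)
        ax.legend(fontsize="small")
    else:
        ax.plot(trace["generation"], trace["pi"])
    ax.set_xlabel("generation")
    ax.set_ylabel(r"$\pi$ per site")
    return ax
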