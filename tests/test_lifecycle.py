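"""The family lifecycle: pairing, litters, social interaction, regulation,
burn-in, insertion, and replicate runs."""

import numpy as np
import pytest

from sibaltruism.genetics import GenomeParams, Haplotype, Individual
from sibaltruism.lifecycle import (
    ExtinctionError,
    Juveniles,
    LifecycleParams,
    Population,
    assign_social_pair,
    burn_in,
    insert_altruistic_allele,
    pair_adults,
    reproduce,
    reproduce_litter,
    run_replicate,
    social_adjustment,
    step,
    viability_and_regulation,
    _social_pair_indices,
)

NEUTRAL_GENOME = GenomeParams(u_del=0.0, s_del=0.0)


def neutral_pop(n, seed=0, K=None):
    return Population.founders(NEUTRAL_GENOME, n, np.random.default_rng(seed))


def carrier_individual():
    return Individual(hap_a=Haplotype(has_altruism=True), hap_b=Haplotype())


class TestPairing:
    @pytest.mark.parametrize("n,n_pairs,n_unpaired", [(1000, 500, 0), (2, 1, 0), (3, 1, 1)])
    def test_pair_counts(self, n, n_pairs, n_unpaired):
        mothers, fathers = pair_adults(neutral_pop(n), np.random.default_rng(1))
        assert mothers.size == fathers.size == n_pairs
        used = np.concatenate([mothers, fathers])
        assert np.unique(used).size == used.size  # disjoint, no self-pairing
        assert n - used.size == n_unpaired

    def test_fewer_than_two_adults_is_extinction(self):
        with pytest.raises(ExtinctionError):
            pair_adults(neutral_pop(1), np.random.default_rng(0))


class TestReproduction:
    def test_litter_of_four_sharing_litter_id(self):
        rng = np.random.default_rng(2)
        mother, father = carrier_individual(), Individual(Haplotype(), Haplotype())
        litter = reproduce_litter(mother, father, NEUTRAL_GENOME, LifecycleParams(K=10), rng, litter_id=9)
        assert len(litter) == 4
        assert all(j.litter_id == 9 and j.stage == "juvenile" for j in litter)

    def test_monomorphic_parents_give_identical_litter(self):
        rng = np.random.default_rng(3)
        parent_hap = Haplotype(np.array([11, 40], dtype=np.int64))
        mother = Individual(parent_hap, parent_hap)
        father = Individual(parent_hap, parent_hap)
        litter = reproduce_litter(mother, father, NEUTRAL_GENOME, LifecycleParams(K=10), rng)
        for j in litter:
            assert j.hap_a == parent_hap and j.hap_b == parent_hap

    def test_mendelian_segregation_of_altruism_allele(self):
        """Het carrier x non-carrier: each offspring inherits the allele with
        probability 1/2 (checked over 1e4 litters via the cohort engine)."""
        pop = neutral_pop(2)
        pop.alt[0] = True  # individual 0 heterozygous
        n_litters = 10_000
        mothers = np.zeros(n_litters, dtype=np.int64)
        fathers = np.ones(n_litters, dtype=np.int64)
        juv = reproduce(pop, mothers, fathers, LifecycleParams(K=10), np.random.default_rng(4))
        pheno = juv.alt[0::2] | juv.alt[1::2]
        frac = pheno.mean()
        se = 0.5 / np.sqrt(juv.n)
        assert abs(frac - 0.5) < 3 * se


class TestSocialInteraction:
    def test_exactly_two_siblings_flagged(self):
        litter = [Individual(Haplotype(), Haplotype()) for _ in range(4)]
        i, j = assign_social_pair(litter, np.random.default_rng(0))
        assert i != j
        flagged = [k for k, ind in enumerate(litter) if ind.social_partner is not None]
        assert sorted(flagged) == sorted([i, j])

    def test_pair_choice_uniform_over_six_pairs(self):
        """Chi-square on the 6-way multinomial over 6e4 litters."""
        from scipy.stats import chisquare

        a, b = _social_pair_indices(60_000, 4, np.random.default_rng(8))
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        pair_id = lo * 4 + hi
        _, counts = np.unique(pair_id, return_counts=True)
        assert counts.size == 6
        assert chisquare(counts).pvalue > 1e-3

    @pytest.mark.parametrize(
        "self_alt,partner_alt,expected",
        [(True, True, 0.3 - 0.1), (True, False, -0.1), (False, True, 0.3), (False, False, 0.0)],
    )
    def test_social_adjustment(self, self_alt, partner_alt, expected):
        life = LifecycleParams(K=10, c=0.1, b=0.3)
        me = carrier_individual() if self_alt else Individual(Haplotype(), Haplotype())
        other = carrier_individual() if partner_alt else Individual(Haplotype(), Haplotype())
        assert social_adjustment(me, other, life) == pytest.approx(expected)


class TestViabilityAndRegulation:
    def make_juveniles(self, n, alt=None):
        return Juveniles(
            haps=[np.empty(0, dtype=np.int64)] * (2 * n),
            alt=np.zeros(2 * n, dtype=bool) if alt is None else alt,
            src=np.zeros(2 * n, dtype=np.int64),
            n=n,
        )

    def test_density_regulation_halves_2000_juveniles_at_K1000(self):
        pop = neutral_pop(1000, seed=5)
        juv = self.make_juveniles(2000)
        a, b = _social_pair_indices(500, 4, pop.rng)
        viability_and_regulation(pop, juv, LifecycleParams(K=1000), pop.rng, a, b)
        se = np.sqrt(2000 * 0.25)
        assert abs(pop.n - 1000) < 4 * se
        assert pop.generation == 1

    def test_undercrowded_cohort_all_survive(self):
        pop = neutral_pop(100, seed=6)
        juv = self.make_juveniles(80)
        a, b = _social_pair_indices(20, 4, pop.rng)
        viability_and_regulation(pop, juv, LifecycleParams(K=1000), pop.rng, a, b)
        assert pop.n == 80

    def test_homozygous_lethal_juveniles_never_survive(self):
        genome = GenomeParams(u_del=1e-8, s_del=-1.0)
        pop = Population.founders(genome, 8, np.random.default_rng(7))
        n = 8
        juv = Juveniles(
            haps=[np.array([50], dtype=np.int64)] * (2 * n),  # hom lethal everywhere
            alt=np.zeros(2 * n, dtype=bool),
            src=np.zeros(2 * n, dtype=np.int64),
            n=n,
        )
        a, b = _social_pair_indices(2, 4, pop.rng)
        with pytest.raises(ExtinctionError):
            viability_and_regulation(pop, juv, LifecycleParams(K=1000), pop.rng, a, b)


class TestInsertion:
    def test_single_copy_at_known_frequency(self):
        """K=100: 100 parents + 200 juveniles -> 600 chromosomes -> p0=1/600."""
        pop = neutral_pop(100, seed=9)
        mothers, fathers = pair_adults(pop, pop.rng)
        juv = reproduce(pop, mothers, fathers, LifecycleParams(K=100), pop.rng)
        p0 = insert_altruistic_allele(pop, juv, pop.rng)
        assert p0 == pytest.approx(1.0 / 600.0, abs=0)
        assert pop.alt.sum() + juv.alt.sum() == 1

    def test_insertion_refused_when_allele_present(self):
        pop = neutral_pop(10, seed=10)
        pop.alt[0] = True
        juv = TestViabilityAndRegulation().make_juveniles(4)
        with pytest.raises(ValueError):
            insert_altruistic_allele(pop, juv, pop.rng)


class TestBurnIn:
    def test_zero_burn_in_returns_mutation_free_population(self):
        life = LifecycleParams(K=50, burn_in_gens=0)
        pop, trace = burn_in(NEUTRAL_GENOME, life, seed=1)
        assert pop.n == 50
        assert all(h.size == 0 for h in pop.haps)
        assert not pop.alt.any()
        assert trace[-1][1] == 0.0

    def test_background_selection_lowers_equilibrium_diversity(self):
        """Stronger purifying selection on linked sites lowers the diversity
        plateau relative to neutral linked mutations (the qualitative
        trajectory signature; desk scale, mean over seeded runs)."""
        life = LifecycleParams(K=50, burn_in_gens=400)
        pis = {}
        for s_del in (0.0, -0.1):
            genome = GenomeParams(u_del=1e-6, s_del=s_del)
            vals = [
                burn_in(genome, life, seed=1000 + 7 * i + int(s_del < 0), record_pi_every=0)[0]
                for i in range(8)
            ]
            from sibaltruism.stats import heterozygosity_pi

            pis[s_del] = np.mean([heterozygosity_pi(p) for p in vals])
        assert pis[-0.1] < pis[0.0]

    def test_extinction_during_burn_in_raises(self):
        genome = GenomeParams(u_del=1e-2, s_del=-1.0)  # ~1000 lethals per gamete
        life = LifecycleParams(K=4, burn_in_gens=5)
        with pytest.raises(ExtinctionError):
            burn_in(genome, life, seed=0)


class TestReplicates:
    def test_identical_snapshot_and_seed_give_identical_outcome(self, neutral_seed_pop):
        life = LifecycleParams(K=100, c=0.1, b=0.3, burn_in_gens=0)
        a = run_replicate(neutral_seed_pop, life, 777)
        b = run_replicate(neutral_seed_pop, life, 777)
        assert a == b

    def test_snapshot_roundtrip_preserves_dynamics(self, neutral_seed_pop, tmp_path):
        path = tmp_path / "snap.json"
        neutral_seed_pop.save(path)
        restored = Population.load(path)
        life = LifecycleParams(K=100, c=0.1, b=0.3, burn_in_gens=0)
        assert run_replicate(restored, life, 42) == run_replicate(neutral_seed_pop, life, 42)

    def test_censoring_flagged_not_reported_as_loss(self, neutral_seed_pop):
        life = LifecycleParams(K=100, c=0.0, b=0.0, burn_in_gens=0, max_gens=2)
        outcomes = [run_replicate(neutral_seed_pop, life, s) for s in range(60)]
        censored = [o for o in outcomes if o.censored]
        assert censored, "expected some replicates still segregating at the cap"
        assert all(not o.fixed and o.generations == 2 for o in censored)

    def test_neutral_fixation_fraction_near_p0_smoke(self, neutral_seed_pop):
        """Quick neutral-martingale sanity check (the full-scale version backs
        the acceptance suite)."""
        from sibaltruism.stats import estimate_fixation

        life = LifecycleParams(K=100, c=0.0, b=0.0, burn_in_gens=0)
        outs = [
            run_replicate(neutral_seed_pop, life, ss)
            for ss in np.random.SeedSequence(31).spawn(6000)
        ]
        est = estimate_fixation(outs, level=0.99)
        assert est.ci_low <= 1.0 / 600.0 <= est.ci_high

    def test_nonoverlapping_generations_counter(self, neutral_seed_pop):
        pop = neutral_seed_pop.copy(rng=np.random.default_rng(3))
        g0 = pop.generation
        step(pop, LifecycleParams(K=100))
        assert pop.generation == g0 + 1


class TestEquilibriumAndSelectionDifferential:
    def test_adult_count_stays_near_carrying_capacity(self):
        """Post-burn-in adult numbers stay within [0.9 K, 1.05 K] under the
        full-scale parameters (slight deficit from the mutation load)."""
        genome = GenomeParams(s_del=-0.01)
        life = LifecycleParams(K=1000, burn_in_gens=300)
        pop, _ = burn_in(genome, life, seed=77, record_pi_every=0)
        counts = []
        for _ in range(300):
            step(pop, life)
            counts.append(pop.n)
        counts = np.array(counts)
        # equilibrium level sits in [0.9K, 1.05K]; instantaneous counts
        # additionally fluctuate binomially (sd ~ sqrt(K/4) ~ 16)
        assert 0.9 * life.K <= counts.mean() <= 1.05 * life.K
        assert counts.min() >= 0.85 * life.K
        assert counts.max() <= 1.1 * life.K

    @staticmethod
    def exact_delta_x(x, b, c):
        """Family-enumeration oracle for the expected one-generation change in
        allele frequency (large-N limit; density factor cancels)."""
        GAM = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        p = np.array([(1 - x) ** 2, 2 * x * (1 - x), x**2])
        gvec = np.arange(3.0)
        phi = np.array([0.0, 1.0, 1.0])
        num = den = 0.0
        for i in range(3):
            for j in range(3):
                P = p[i] * p[j]
                if P == 0:
                    continue
                q = np.zeros(3)
                for a in (0, 1):
                    for b_ in (0, 1):
                        q[a + b_] += GAM[i, a] * GAM[j, b_]
                Eg, Ephi, Egphi = q @ gvec, q @ phi, q @ (gvec * phi)
                num += P * (2 * (Eg - c * Egphi + b * Eg * Ephi) + 2 * Eg)
                den += P * (2 * (1.0 + (b - c) * Ephi) + 2.0)
        return num / (2 * den) - x

    def test_exact_neutrality_at_hamilton_threshold(self):
        """At b = c/r the enumerated expected frequency change is exactly zero
        at every frequency."""
        for x in (0.01, 0.1, 0.3, 0.6, 0.9):
            assert abs(self.exact_delta_x(x, b=0.2, c=0.1)) < 1e-14

    def test_simulated_selection_differential_matches_enumeration(self):
        """Mean one-generation Delta-p at x0 = 0.3, b = 0.3 matches the exact
        family-enumeration value within 3 SE (and the diffusion drift term
        S x(1-x)(1-x) with S = (-c + b/2)/2 within 10%)."""
        genome = NEUTRAL_GENOME
        life = LifecycleParams(K=1000, c=0.1, b=0.3, burn_in_gens=0)
        x0, trials = 0.3, 700
        dps = []
        for ss in np.random.SeedSequence(99).spawn(trials):
            rng = np.random.default_rng(ss)
            pop = Population.founders(genome, 1000, rng)
            pop.alt = rng.random(2000) < x0
            before = pop.alt.mean()
            step(pop, life)
            dps.append(pop.alt.mean() - before)
        mean, se = np.mean(dps), np.std(dps) / np.sqrt(trials)
        exact = self.exact_delta_x(x0, b=0.3, c=0.1)
        assert abs(mean - exact) < 3 * se
        S = (-0.1 + 0.5 * 0.3) / 2
        assert exact == pytest.approx(S * x0 * (1 - x0) ** 2, rel=0.10)
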