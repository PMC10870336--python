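# Methods

## Model

`sibaltruism` simulates the fate of a single altruism allele in a
family-structured population of diploid, sexually reproducing, recombining
individuals, under linked purifying selection (background selection), and
compares the simulated fixation probabilities with diffusion-theory
predictions.

### Genome

Each individual carries two haplotypes of one contiguous region of
`L = 100,000` bp (1-based coordinates). Haplotypes are sparse sorted integer
multisets of deleterious-mutation positions plus a boolean for the altruism
allele at bp 1000. Per gamete, the crossover count is Poisson(ρ·(L−1)) with
breakpoints uniform on the interior (the per-interval map length; the
difference from ρ·L is a part in 10⁵), and the new-mutation count is
Poisson(u·L) with positions uniform on [1, L] excluding the altruism locus.
Defaults: ρ = 10⁻⁸/bp, u = 5×10⁻⁸/bp, deleterious dominance h = 0.5,
selection coefficient s on a grid from 0 to −1. Fitness is multiplicative
across sites: (1 + hs) per heterozygous and (1 + s) per homozygous site.
Stacked mutations (two copies at one position on one haplotype) each
contribute a factor; at the default rates collisions are vanishingly rare.
Mutations fixed in every chromosome are substituted out each generation,
which rescales all fitnesses equally and keeps memory bounded.

### Lifecycle

Generations are non-overlapping. Each cycle: (1) adults are paired by a
uniform random perfect matching (an odd leftover neither reproduces nor
survives); (2) each pair produces a litter of four full siblings; (3) in
each litter one sibling pair, uniform over the six possible pairs, interacts
socially: a carrier of the (completely dominant) altruism allele pays
survival cost `c` and grants its partner survival benefit `b`; bystanders
are unaffected; (4) each juvenile survives with probability

    clamp( min(1, K/N_juv) · (w_del + b·[partner altruist] − c·[self altruist]), 0, 1 )

and survivors mature while all parents die. With carrying capacity
K = 1000 this settles at ~1000 adults and ~2000 juveniles, so juvenile
survival is ~1/2 (slightly modulated by the deleterious load).

The social terms act on the *fitness scale* (baseline 1) and are then
multiplied by the density factor. This detail fixes the realized selection
coefficient of the allele. Only then does the per-generation selection
coefficient equal half the inclusive fitness effect,
𝒮 = (−c + r·b)/2 with sibling relatedness r = 1/2 (the 1/2 outside because
only one of the two sibling pairs interacts), and only then is the allele
*exactly* neutral at b = c/r: an exact family-enumeration calculation
(reproduced in the test suite) shows E[Δp] ≡ 0 at every allele frequency
when −c + rb = 0, while the measured E[Δp] elsewhere matches the diffusion
drift term 𝒮·x(1−x)(1−x) of a dominant allele within a few percent at low
and intermediate frequency (deficit growing to ~9% near fixation). Two
tempting alternatives fail: adding the deltas *after* the density product
doubles the relative selection intensity (baseline survival is ~1/2), and
fully multiplicative factors (1−c)(1+b) introduce a −cb cross term that
breaks neutrality at b = c/r. A multiplicative variant is still available
via `LifecycleParams(social_mode="multiplicative")` for sensitivity
analyses.

Replicates: a burn-in of 5000 generations (full scale) without the allele
brings the population to mutation–selection balance; a single allele copy is
then inserted into a uniformly chosen chromosome while parents and offspring
coexist (2·(N_parents + N_juv) = 6000 chromosomes at K = 1000, hence
p₀ = 1/6000; a copy landing on a parent chromosome dies with it — the
counting still makes the neutral fixation probability exactly p₀, which the
test suite verifies by simulation). The replicate runs to loss or fixation;
hitting the generation cap (default 40·K) is reported as censored, never as
loss.

### Theory

The diffusion fixation probability of an allele with dominance h and
selection coefficient 𝒮 at initial frequency p₀ in a population of
effective size Nₑ is

    p_fix = ∫₀^{p₀} ψ(x) dx / ∫₀^1 ψ(x) dx,
    ψ(x) = exp(−2Nₑ𝒮 x (2h + x(1−2h))),

computed by adaptive Gauss–Kronrod quadrature at relative tolerance 10⁻¹⁰
with the exponent shifted by its maximum over [0, 1] (a log-sum-exp guard),
so the ratio stays finite for |2Nₑ𝒮| of order 10⁴ and beyond. For the
altruism allele h = 1 (complete dominance).

The family lifecycle is not Wright–Fisher: tracking, for every chromosome,
how many copies of the neutral bp-1000 locus survive into the next
generation gives a variance in reproductive success σ² ≈ 0.75 rather than 1
(each chromosome transmits ≈ Binomial(4, 1/4) copies: four offspring, half
inherit, half of those survive; 4·(1/4)·(3/4) = 0.75). Hence
Nₑ ≈ N/σ² ≈ 1333 at N = 1000.

Background selection rescales the effective size. For a focal locus at one
end of a region with total diploid deleterious rate U = 2ul and map length
R = ρl Morgans,

    Nₑ,bg = Nₑ · exp(−U / (2|s·h| + R)),

the Hudson–Kaplan approximation, which reduces to the classic
no-recombination load result Nₑ·e^{−U/(2hs)} as R → 0. The exponent grouping
U/(2|sh| + R) is adopted on that limit's authority. At the defaults
(U = 10⁻², R = 10⁻³, s = −0.01, h = 0.5) the reduction factor is
e^{−10/11} ≈ 0.40. Strongly deleterious linked mutations (s = −1) give a
factor ≈ 0.99 — effectively no background selection — and s = 0 leaves Nₑ
unchanged by construction, so both serve as no-BGS controls.

Hamilton's rule: the allele is favored iff b > c/r; with c = 0.1 and
r = 1/2 the critical benefit is 0.2.

## Statistics

Fixation probabilities are binomial fractions with exact Clopper–Pearson
intervals (normal approximations misbehave at p ~ 10⁻⁴; censored replicates
are excluded and counted separately). Nucleotide diversity is
π = Σ 2p(1−p)·2N/(2N−1) / L over all chromosomes (presence per haplotype),
identical to all-pairs mismatch counting, verified exactly in the tests.
σ² pools per-chromosome transmitted-copy counts across generations and
runs (sample variance; the first 10 generations of each run are discarded
as demographic transient). The fixation regression is a binomial GLM fitted
by IRLS (`fixed ~ benefit + BGS + benefit×BGS`, benefit untransformed, BGS
a 0/1 flag that is 0 when s = 0 or s = −1); complete separation is flagged
and reported as non-finite coefficients.

## Desk-scale study conditions

The full-scale experiment (K = 1000, 10⁶ replicates per grid cell) is
cluster-scale; the package exposes it as the `full` preset but the test
suite and worked examples use a `desk` preset chosen once from a scaling
analysis:

- K = 100 (Nₑ ≈ 133), p₀ = 1/600, burn-in 400 generations (the
  mutation–selection-balance timescale is 1/(h|s|) ≈ 17 generations at the
  desk s, and diversity equilibrates on ~4Nₑ,bg ≈ 100 generations).
- Background-selection intensity is rescaled to preserve the dimensionless
  regime rather than the raw parameters: at K = 100 the full-scale
  s = −0.01 gives Nₑ·s·h ≈ 0.67 < 1, i.e. the "deleterious" mutations
  drift and background selection all but vanishes. The desk preset uses
  s = −0.06 and u = 5×10⁻⁷ (U = 0.1), keeping Nₑ·s·h = 4 and predicting a
  diversity reduction B = e^{−0.1/0.061} ≈ 0.19; the measured π ratio in a
  4-seed burn-in comparison was 0.21.
- Replicate counts per cell (5,000 on the favored side b = 0.3, 30,000 on
  the disfavored side b = 0.16) were sized by a power analysis on the
  diffusion predictions so each directional comparison has a multi-sigma
  expected separation.

At this scale 2Nₑ𝒮 is of order 1–10, where the h = 1 diffusion formula is
only approximate (the simulated fixation probability of the favored allele
runs ~20% below the Eq.-style prediction, consistent with the
high-frequency drift-term deficit noted above). The desk-scale checks are
therefore directional and CI-based, not point comparisons with the
analytic values; quantitative agreement with the diffusion predictions is
asserted only where it is exact (neutrality, p₀ accounting, σ², closed
forms). The low-recombination amplification of background selection
(ρ = 10⁻¹² vs 10⁻⁸) changes the predicted reduction factor by only ~3% at
desk scale — far below simulation resolution — so that direction is checked
through the analytic pipeline, while the high-recombination erasure
(ρ = 10⁻⁴, R = 10) is large and is checked by simulation.

## What the generator does and does not emulate

The synthetic populations reproduce the study's design: constant carrying
capacity, obligate monogamous pairing with litters of exactly four, a
single social interaction per litter, one linked region with uniform
mutation and recombination rates, and a single-locus, fully dominant social
trait. Real populations violate most of these (variable litter sizes,
age structure, migration, variable recombination maps, polygenic sociality);
passing tests therefore demonstrate the internal consistency of model,
theory, and estimators, not field realism.

## Numerical choices and degenerate inputs

Zero rates (ρ = 0, u = 0) are valid and exact (gamete = parental
haplotype). Survival probabilities are clamped to [0, 1] after all
adjustments. Extinction (fewer than two adults, or a cohort with no
survivors) raises an explicit error during burn-in and is recorded as loss
within a replicate (possible only at tiny K). Replicate RNG streams are
spawned from a master `SeedSequence` by counter, so replicates are
order-independent and each is reproducible from `(snapshot, replicate_seed)`
alone; snapshots serialize the full RNG state in versioned JSON.

## Known limitations

- The diffusion comparison degrades at small 2Nₑ𝒮 (desk scale), as
  documented above.
- The Hudson–Kaplan Nₑ,bg treats background selection as a pure Nₑ
  rescaling; interference between the deleterious background and the focal
  sweep beyond that rescaling is outside the model (by design — it is the
  null hypothesis under test).
- σ² is measured in the neutral lifecycle; with strong deleterious load the
  variance in reproductive success, and hence Nₑ, shifts slightly.
- The π estimator uses all chromosomes with the 2N/(2N−1) correction;
  trajectories are recorded every 100 generations during burn-in to keep
  traces light.
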