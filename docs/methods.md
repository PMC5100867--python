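# Methods

## Model and assumptions

One autosomal locus, four allele states: `WT` (intact, cleavable), `GD`
(homing drive cassette: Cas9 + gRNA), `R` (resistant via germline NHEJ),
`R*` (resistant via the zygotic maternal effect). `R` and `R*` are the
same mutated target site; the star is provenance bookkeeping only, and it
resets at meiosis (an `R*` allele is transmitted as `R`).

A cross composes three operators, enumerated exactly:

1. **Germline homing.** Modelled per individual germline genotype: in a
   parent carrying ≥ 1 `GD`, each `WT` allele becomes `GD` with
   probability `x` (HDR) else `R` (NHEJ). A per-gamete formulation gives
   the identical transmitted-allele marginal for heterozygotes; the
   per-individual form matches the "success rate of homing" framing and
   keeps enumeration simple. Resistant alleles are never cut again: the
   target site is destroyed, so homing acts only on `WT` partners.
2. **Mendelian segregation.** Each germline allele transmitted with
   probability ½.
3. **Zygotic maternal effect.** A mother deposits editing activity iff
   her own genome carries ≥ 1 `GD` allele (the cassette carries both
   Cas9 and gRNA). Each `WT` allele of the zygote — including a
   maternally inherited one — is then independently mutated to `R*` with
   probability `y`. Independence per allele is a closure choice: the
   defining pedigree never exercises the two-WT-allele case from a drive
   mother. Grand-maternal carry-over (a drive-free mother who was herself
   maternally loaded) is not modelled; one generation of carry-over is
   demonstrated experimentally but no second-generation rate exists to
   calibrate it.

Failed HDR always yields a resistant allele (the strict `1 − x → R`
dichotomy); still-cleavable NHEJ products are not modelled.

Offspring sex is assigned 1:1 independent of genotype. All genotypes have
equal viability and fertility by default; `cross()` exposes a per-genotype
relative-fitness mapping that defaults to neutrality.

**Arithmetic.** All enumeration uses `fractions.Fraction`; floats given as
parameters are read through their shortest decimal representation
(`0.95` → 19/20), so distribution sums equal 1 exactly and reported
probabilities are exact rationals. Percentages are rendered by
round-half-even at the quoted number of decimals (one decimal for the
heterozygote figures, two for the homozygote).

## Parameters

| name | meaning | domain | default |
|---|---|---|---|
| `x` | germline HDR homing success per WT allele in a drive carrier | [0, 1] | 0.95 in the worked example (reported homing efficiencies are 91–99 %) |
| `y` | zygotic maternal-effect mutation per WT allele, drive mother | [0, 1] | 0.87 in the worked example (the measured germline disruption rate in component-free progeny of drive mothers, 87.2 %) |

## The two-generation pedigree and its toggle

`g2_backcross(params, maternal_effect)`: G0 = GD/WT male × WT female; G1
pooled at an exact 1:1 sex ratio; every G1 individual backcrossed to wild
type; the maternal-effect operator acts only in crosses whose mother is a
G1 drive carrier, and only when the toggle is on. The 1:1 weighting is
required by the factor ½ in R/R\* = ½ · 0.975 · 0.025 · 0.87 = 1.06 %;
offspring of all G1 parents are pooled with equal weight.

With x = 0.95, y = 0.87 the enumeration gives R/+ = 0.026271875 (2.6 %)
with the toggle on and 0.0368750 (3.7 %) with it off. The published
summary pairs 2.6 % with the maternal-effect-excluded reading and 3.7 %
with the included one — the reverse of this enumeration. Note that the
off-value equals the on-values summed over both resistant classes
(2.6271875 + 1.0603125 = 3.6875 exactly), because the maternal effect
moves exactly the R/R\* mass out of R/+, which likely explains the
labelling: 3.7 % is also the total resistant-carrying heterozygote-plus-
homozygote frequency once maternal effects act. Both toggle settings are
exposed rather than silently choosing a reading; the toggle pair produces
both quoted numbers either way.

## Population dynamics

Two schemes. `backcross_to_wildtype`: every individual mates a WT partner
(an invading drive so rare that carriers never meet). `random_mating`:
panmixia by genotype-by-sex frequency products, seeded by a release in
which a fraction *r* of the population is GD/WT males and the remainder
wild type split equally by sex. The deterministic recursion mixes exact
`cross()` outputs and is fully rational. `wright_fisher` draws, each
generation, `pop_size` offspring in one multinomial step over
genotype×sex cells from the exact offspring distribution given the
realised parental frequencies — simple non-overlapping generations, no
age structure, no selection unless a fitness mapping is supplied. One
seeded `numpy` generator owns all randomness; equal seeds give identical
trajectories. The deterministic recursion is the infinite-population
limit; the test suite verifies the mean of 200 replicates at N = 10⁴
stays within 3 empirical standard errors of it over 5 generations (sizes
chosen to make the check sharp at negligible runtime).

## Estimation

Progeny-class counts (GAL4+, dGAL4, QF2+) per cross are trinomial with
probabilities (1 − d, d(1 − h), dh): `d` is the total disruption rate of
the targeted GAL4 allele, `h` the HDR fraction among disrupted alleles.
MLEs are the observed proportions; intervals are Wilson score at 95 %
(Wald degenerates at the observed rates near 1, e.g. 98.2 % at n = 164).
When all progeny lack genomic Cas9/gRNA but the mother carried both, `d`
estimates the maternal-effect germline rate — the model's `y`. Rate
contrasts use Newcombe score intervals for a difference of proportions;
no p-values are reported because the underlying experiments report
proportions, not tests. Exact coverage of the Wilson interval (computed
from the binomial pmf) is 93–97 % across most of the design grid but
92.2 % at (p = 0.98, n = 50) and 97.0 % at (p = 0.982, n = 164) — the
known oscillation of score intervals; the suite therefore checks
empirical coverage against the exact value per cell and the 93–97 % band
on the grid-pooled coverage. For a truth on the boundary (h = 0) any
interval containing the point estimate covers with probability 1, so
only containment is checked there. Statsmodels' Wilson evaluation leaves
floating-point noise at the boundaries (lower bound ~1e-18 at zero
successes); `fit_trinomial` snaps those bounds to exact 0/1.

Published class counts were not released; fixtures reconstruct them as
`round(percentage × n)` (e.g. 360/413 for 87.2 %) and are labelled
reconstructions — the printed percentage and n are the data.

## Synthetic data

`simulate_germline_counts` draws trinomial class counts at true (d, h)
per cross; the default four-cross fixture mirrors the experimental design
(both components / Cas9 only / gRNA only / no components) at d =
0.982/0.92/0.97/0.872, n = 164/200/200/413, with h = 0.1 where a donor
cassette is present (the ~10 % HDR-vs-NHEJ scale reported for the donor's
genomic site) — paper-inspired values, not measurements.
`simulate_brain_counts` draws per-brain labelled-cell counts out of
100,000 neurons, binomial by default; a beta-binomial knob `rho`
(intra-class correlation, mean-matched) models clonal correlation from
early-embryo editing. It defaults to 0: the published ± figures are not
identified as SD or SEM, so no calibration to them is attempted.
`simulate_drive_cohort` draws each generation's cohort independently from
the deterministic trajectory's exact genotype distribution. All
generators are bit-reproducible given (spec, seed).

What passing tests show — and don't: the generators share the model's
independence assumptions (per-cell, per-allele, per-individual), so
recovery and coverage results validate the estimators under the model,
not against brood-structure correlation (germline mosaicism within one
father), clonal somatic editing, or fitness differences in real data.

## Numerical and design notes

- Exact rational arithmetic everywhere in enumeration; floats only at the
  sampling and estimation boundary.
- Distribution constructors reject negative weights and totals differing
  from 1 (exactly for rationals, 1e-12 for floats).
- Degenerate inputs: h is reported 0 with a flagged vacuous [0, 1]
  interval when no disrupted progeny exist; all-zero count rows,
  empty tables, one-sex populations and pop_size < 2 raise.
- Output TSVs embed a `#` provenance header (version, command,
  parameters, seed) and deliberately no timestamp, so a recorded config
  reproduces its output byte-identically.
- Monte-Carlo cross-validation uses an independently coded vectorised
  sampler of the same three mechanistic steps; it shares no enumeration
  code and is compared per genotype class in binomial-SE units.

## Known limitations

Single locus, single gRNA, no sex linkage; no fitness costs by default;
no spatial structure, migration or density dependence; no evolution of
cutting rates; no grand-maternal carry-over; no brood-level
overdispersion in germline transmission.
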