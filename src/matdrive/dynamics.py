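"""Multi-generation drive dynamics: the two-generation backcross pedigree,
deterministic (infinite-population) recursions, and a Wright–Fisher
stochastic counterpart.

Two mating schemes are supported:

* ``backcross_to_wildtype`` — every individual is mated to a wild-type
  partner each generation (the pedigree used for the worked example:
  a drive-heterozygous male released into a wild-type population so large
  that drive carriers never meet).
* ``random_mating`` — panmictic mating by genotype-by-sex frequencies,
  seeded by a release of drive-heterozygous males at a given fraction.

Sex is assigned 1:1 independent of genotype (autosomal drive); offspring of
all parents are pooled with equal weight (no fecundity differences).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .alleles import ALL_GENOTYPES, WILDTYPE, Allele, Genotype, parse_genotype
from .model import DriveParams, GenotypeDistribution, cross_cached

__all__ = [
    "Sex",
    "PopulationState",
    "MatingScheme",
    "Trajectory",
    "g2_backcross",
    "propagate",
    "wright_fisher",
    "release_state",
]


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class MatingScheme:
    """How mates are paired each generation."""

    kind: str  # "backcross_to_wildtype" | "random_mating"
    release_fraction: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        if self.kind not in ("backcross_to_wildtype", "random_mating"):
            raise ValueError(f"unknown mating scheme {self.kind!r}")
        r = Fraction(self.release_fraction) if not isinstance(
            self.release_fraction, float) else Fraction(repr(self.release_fraction))
        if not 0 <= r <= 1:
            raise ValueError("release_fraction must lie in [0, 1]")
        object.__setattr__(self, "release_fraction", r)


@dataclass
class PopulationState:
    """Genotype-by-sex frequencies at one generation."""

    frequencies: dict[tuple[Genotype, Sex], Fraction]
    generation: int = 0

    def __post_init__(self) -> None:
        freqs: dict[tuple[Genotype, Sex], Fraction] = {}
        for (g, sex), f in self.frequencies.items():
            f = Fraction(f) if not isinstance(f, float) else Fraction(repr(f))
            if f < 0:
                raise ValueError(f"negative frequency for {g.label}/{sex}")
            if f:
                key = (g.canonical(), sex)
                freqs[key] = freqs.get(key, Fraction(0)) + f
        total = sum(freqs.values(), Fraction(0))
        if abs(total - 1) > Fraction(1, 10**9):
            raise ValueError(f"frequencies sum to {float(total)}, not 1")
        self.frequencies = freqs

    def genotype_frequencies(self) -> dict[Genotype, Fraction]:
        out: dict[Genotype, Fraction] = {}
        for (g, _), f in self.frequencies.items():
            out[g] = out.get(g, Fraction(0)) + f
        return out

    def sex_conditional(self, sex: Sex) -> dict[Genotype, Fraction]:
        """Genotype distribution among individuals of one sex."""
        sub = {g: f for (g, s), f in self.frequencies.items() if s is sex}
        total = sum(sub.values(), Fraction(0))
        if total == 0:
            raise ValueError(f"no {sex.value}s present in the population")
        return {g: f / total for g, f in sub.items()}

    def allele_frequencies(self) -> dict[Allele, Fraction]:
        out = {a: Fraction(0) for a in Allele}
        for (g, _), f in self.frequencies.items():
            for a in g:
                out[a] += f / 2
        return out


@dataclass
class Trajectory:
    """Ordered generation states plus per-generation allele frequencies."""

    states: list[PopulationState] = field(default_factory=list)

    @property
    def allele_frequencies(self) -> list[dict[Allele, Fraction]]:
        return [s.allele_frequencies() for s in self.states]

    def genotype_frequency(self, generation: int, label: str) -> Fraction:
        gf = self.states[generation].genotype_frequencies()
        return gf.get(parse_genotype(label).canonical(), Fraction(0))


def release_state(scheme: MatingScheme) -> PopulationState:
    """Initial population for a scheme.

    For random mating, a fraction ``release_fraction`` of the population is
    drive-heterozygous (GD/WT) males; the remainder is wild type, split
    equally between the sexes.  For the backcross scheme the released
    individuals are the whole modelled cohort (partners are drawn from an
    unmodelled wild-type pool), so the state is 100% GD/WT males.
    """
    gdwt = parse_genotype("GD/WT")
    if scheme.kind == "backcross_to_wildtype":
        return PopulationState({(gdwt, Sex.MALE): Fraction(1)})
    r = scheme.release_fraction
    freqs = {(gdwt, Sex.MALE): r}
    if r < 1:
        freqs[(WILDTYPE, Sex.MALE)] = (1 - r) / 2
        freqs[(WILDTYPE, Sex.FEMALE)] = (1 - r) / 2
    return PopulationState(freqs)


def _offspring_distribution(
    state: PopulationState,
    scheme: MatingScheme,
    params: DriveParams,
    maternal_effect: bool,
) -> GenotypeDistribution:
    """Exact offspring genotype distribution of one generation of mating."""
    parts: list[tuple[GenotypeDistribution, Fraction]] = []
    if scheme.kind == "backcross_to_wildtype":
        for (g, sex), f in state.frequencies.items():
            mother, father = (g, WILDTYPE) if sex is Sex.FEMALE else (WILDTYPE, g)
            parts.append((cross_cached(mother, father, params, maternal_effect), f))
    else:
        mothers = state.sex_conditional(Sex.FEMALE)
        fathers = state.sex_conditional(Sex.MALE)
        for m, pm in mothers.items():
            for fa, pf in fathers.items():
                parts.append((cross_cached(m, fa, params, maternal_effect), pm * pf))
    return GenotypeDistribution.mixture(parts)


def _split_sexes(dist: GenotypeDistribution, generation: int) -> PopulationState:
    freqs: dict[tuple[Genotype, Sex], Fraction] = {}
    for g, p in dist.unordered().items():
        for sex in Sex:
            freqs[(g, sex)] = p / 2
    return PopulationState(freqs, generation)


def g2_backcross(
    params: DriveParams, maternal_effect: bool = True
) -> GenotypeDistribution:
    """Exact G2 genotype distribution of the two-generation pedigree.

    G0: drive-heterozygous (GD/WT) male x wild-type female.  G1 offspring
    are assigned 1:1 sex, and every G1 individual is backcrossed to wild
    type.  The zygotic maternal-effect operator acts only in crosses whose
    mother is a G1 drive carrier, and only if ``maternal_effect`` — the
    toggle that isolates the contribution of maternal Cas9/gRNA deposition
    to resistance-allele formation.

    With x = 0.95 and y = 0.87 this yields R/+ at 2.6% (toggle on) or 3.7%
    (toggle off), and R/R* at 1.06% (on) or 0 (off).
    """
    g1 = cross_cached(WILDTYPE, parse_genotype("GD/WT"), params, maternal_effect)
    parts: list[tuple[GenotypeDistribution, Fraction]] = []
    for g, p in g1.unordered().items():
        # male G1 parent: wild-type mother, no maternal deposition
        parts.append((cross_cached(WILDTYPE, g, params, maternal_effect), p / 2))
        # female G1 parent: deposition iff she carries the drive
        parts.append((cross_cached(g, WILDTYPE, params, maternal_effect), p / 2))
    return GenotypeDistribution.mixture(parts)


def propagate(
    initial: PopulationState,
    scheme: MatingScheme,
    params: DriveParams,
    n_generations: int,
    maternal_effect: bool = True,
) -> Trajectory:
    """Deterministic (infinite-population) recursion over generations."""
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    traj = Trajectory([initial])
    state = initial
    for gen in range(1, n_generations + 1):
        dist = _offspring_distribution(state, scheme, params, maternal_effect)
        state = _split_sexes(dist, gen)
        traj.states.append(state)
    return traj


# --- Wright–Fisher -------------------------------------------------------

_GENO_INDEX = {g: i for i, g in enumerate(ALL_GENOTYPES)}


def _cross_tensor(params: DriveParams, maternal_effect: bool) -> np.ndarray:
    """T[m, f, o] = P(offspring genotype o | mother m, father f), floats."""
    n = len(ALL_GENOTYPES)
    T = np.zeros((n, n, n))
    for m, mi in _GENO_INDEX.items():
        for f, fi in _GENO_INDEX.items():
            for g, p in cross_cached(m, f, params, maternal_effect).unordered().items():
                T[mi, fi, _GENO_INDEX[g]] += float(p)
    return T


def wright_fisher(
    initial: PopulationState,
    scheme: MatingScheme,
    params: DriveParams,
    pop_size: int,
    n_generations: int,
    seed: int | np.random.Generator,
    maternal_effect: bool = True,
) -> Trajectory:
    """Finite-population stochastic dynamics.

    Each generation, the exact offspring distribution given the realised
    parental frequencies is computed, and ``pop_size`` offspring are drawn
    in a single multinomial step over genotype-by-sex classes (sexes 1:1).
    One seeded generator owns all randomness; identical seeds give
    identical trajectories.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = _cross_tensor(params, maternal_effect)
    n = len(ALL_GENOTYPES)

    # realised counts per (genotype, sex)
    counts = np.zeros((n, 2))  # columns: female, male
    for (g, sex), f in initial.frequencies.items():
        counts[_GENO_INDEX[g], 0 if sex is Sex.FEMALE else 1] += float(f) * pop_size

    traj = Trajectory([initial])
    for gen in range(1, n_generations + 1):
        if scheme.kind == "random_mating":
            fem, mal = counts[:, 0].sum(), counts[:, 1].sum()
            if fem == 0 or mal == 0:
                raise RuntimeError(f"one sex lost at generation {gen}")
            p_m, p_f = counts[:, 0] / fem, counts[:, 1] / mal
            p_off = np.einsum("m,f,mfo->o", p_m, p_f, T)
        else:
            # every individual backcrossed to wild type
            wt = _GENO_INDEX[WILDTYPE]
            freq = counts / counts.sum()
            p_off = np.einsum("m,mo->o", freq[:, 0], T[:, wt, :])
            p_off += np.einsum("f,fo->o", freq[:, 1], T[wt, :, :])
        p_off = np.clip(p_off, 0, None)
        p_off /= p_off.sum()
        cells = (np.outer(p_off, [0.5, 0.5])).ravel()
        counts = rng.multinomial(pop_size, cells).reshape(n, 2).astype(float)
        freqs = {
            (g, sex): Fraction(int(counts[_GENO_INDEX[g], j]), pop_size)
            for g in ALL_GENOTYPES
            for j, sex in ((0, Sex.FEMALE), (1, Sex.MALE))
            if counts[_GENO_INDEX[g], j]
        }
        traj.states.append(PopulationState(freqs, gen))
    return traj
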