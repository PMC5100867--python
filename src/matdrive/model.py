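"""Exact single-cross calculator for a homing drive with dominant maternal effects.

The mechanistic model has two parameters:

* ``x`` — probability that, in the germline of a drive carrier, a wild-type
  partner allele is converted to the drive by HDR ("homing"); with
  probability ``1 - x`` the cut is repaired by NHEJ, producing a resistant
  allele ``R``.
* ``y`` — probability that maternally deposited Cas9/gRNA mutates a
  wild-type allele of the zygote to a resistant allele ``R*``; deposition
  happens iff the mother's own genome carries at least one drive cassette.

A cross is computed by exact enumeration with rational arithmetic:
germline conversion in each parent, Mendelian gamete formation, zygote
assembly, then the zygotic maternal-effect operator.  No sampling anywhere.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from numbers import Rational
from typing import Iterator

import pandas as pd

from .alleles import Allele, Genotype

__all__ = [
    "DriveParams",
    "GenotypeDistribution",
    "GameteDistribution",
    "germline_convert",
    "gametes",
    "maternal_zygotic_effect",
    "cross",
    "round_percent",
]


def round_percent(probability, decimals: int) -> float:
    """Render an exact probability as a percentage, round-half-even.

    Banker's rounding on the exact decimal value, so e.g. Fraction
    339/32000 -> 1.06 (two decimals) without binary-float artefacts.
    """
    from decimal import Decimal

    frac = probability if isinstance(probability, Fraction) else Fraction(repr(float(probability)))
    pct = 100 * frac
    quantum = Decimal(1).scaleb(-decimals)
    return float((Decimal(pct.numerator) / Decimal(pct.denominator)).quantize(quantum))


def as_probability(value, name: str = "probability") -> Fraction:
    """Coerce a number to an exact Fraction in [0, 1].

    Floats are interpreted through their shortest decimal representation
    (``repr``), so ``0.95`` becomes exactly 19/20 rather than the nearest
    binary float.
    """
    if isinstance(value, Rational):
        frac = Fraction(value)
    elif isinstance(value, float):
        frac = Fraction(repr(value))
    elif isinstance(value, str):
        frac = Fraction(value)
    else:
        raise TypeError(f"{name} must be a number, got {type(value).__name__}")
    if not 0 <= frac <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return frac


@dataclass(frozen=True)
class DriveParams:
    """Model parameters: homing success ``x`` and maternal mutation rate ``y``."""

    x: Fraction
    y: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", as_probability(self.x, "x"))
        object.__setattr__(self, "y", as_probability(self.y, "y"))


class _Distribution(Mapping):
    """Immutable finite probability distribution with exact weights."""

    _tol = Fraction(1, 10**12)

    def __init__(self, entries: Mapping | Iterable[tuple]):
        acc: dict = {}
        for key, p in dict(entries).items():
            p = Fraction(p) if isinstance(p, Rational) else Fraction(repr(p))
            if p < 0:
                raise ValueError(f"negative probability for {key}")
            if p:
                acc[key] = acc.get(key, Fraction(0)) + p
        total = sum(acc.values(), Fraction(0))
        if abs(total - 1) > self._tol:
            raise ValueError(f"probabilities sum to {float(total)}, not 1")
        self._entries = acc

    def __getitem__(self, key):
        return self._entries[key]

    def __iter__(self) -> Iterator:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def p(self, key) -> Fraction:
        """Probability of ``key`` (0 if absent)."""
        return self._entries.get(key, Fraction(0))

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{k}: {float(v):.6g}" for k, v in self._entries.items())
        return f"{type(self).__name__}({{{body}}})"


class GameteDistribution(_Distribution):
    """Distribution over transmitted alleles."""


class GenotypeDistribution(_Distribution):
    """Exact probability distribution over diploid genotypes.

    Internally keys may be ordered (parental-origin) genotypes; reporting
    methods collapse to the unordered form.
    """

    def unordered(self) -> dict[Genotype, Fraction]:
        """Collapse to canonical (unordered) genotypes."""
        out: dict[Genotype, Fraction] = {}
        for g, p in self._entries.items():
            c = g.canonical()
            out[c] = out.get(c, Fraction(0)) + p
        return out

    def labels(self) -> dict[str, Fraction]:
        """Map unordered genotype labels (``"GD/WT"``) to probabilities."""
        return {g.label: p for g, p in sorted(
            self.unordered().items(), key=lambda kv: kv[0].label)}

    def p_label(self, label: str) -> Fraction:
        return self.labels().get(label, Fraction(0))

    def allele_frequencies(self) -> dict[Allele, Fraction]:
        """Marginal allele frequencies (mean of the two allele slots)."""
        out = {a: Fraction(0) for a in Allele}
        for g, p in self._entries.items():
            for a in g:
                out[a] += p / 2
        return out

    def summary(self) -> dict[str, Fraction]:
        """Collapse to the drive-literature progeny classes.

        ``drive``: carries >= 1 GD allele; ``resistant_het`` (R/+): one
        resistant allele (R or R*) with one WT; ``resistant_hom``: two
        resistant alleles; ``wildtype``: WT/WT.
        """
        out = {k: Fraction(0) for k in
               ("drive", "resistant_het", "resistant_hom", "wildtype")}
        for g, p in self._entries.items():
            if g.has_drive:
                out["drive"] += p
            elif all(a.resistant for a in g):
                out["resistant_hom"] += p
            elif any(a.resistant for a in g):
                out["resistant_het"] += p
            else:
                out["wildtype"] += p
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Unordered genotype table with probability and percentage columns."""
        rows = [
            {"genotype": g.label, "probability": float(p),
             "percentage": float(100 * p)}
            for g, p in sorted(self.unordered().items(),
                               key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows, columns=["genotype", "probability", "percentage"])

    @staticmethod
    def mixture(
        components: Iterable[tuple["GenotypeDistribution", Fraction]],
    ) -> "GenotypeDistribution":
        """Weighted mixture of genotype distributions (weights sum to 1)."""
        acc: dict[Genotype, Fraction] = {}
        for dist, w in components:
            for g, p in dist.items():
                acc[g] = acc.get(g, Fraction(0)) + w * p
        return GenotypeDistribution(acc)


def germline_convert(parent: Genotype, x) -> GenotypeDistribution:
    """Germline homing: in a drive carrier each WT allele is converted.

    A WT allele becomes GD with probability ``x`` (HDR) or R with
    probability ``1 - x`` (NHEJ).  Resistant alleles are immune (target site
    destroyed), and a parent without a drive allele is returned unchanged:
    no Cas9/gRNA source, no cutting.
    """
    x = as_probability(x, "x")
    if not parent.has_drive:
        return GenotypeDistribution({parent: Fraction(1)})
    outcomes: dict[Genotype, Fraction] = {}
    branches = [
        [(Allele.GD, x), (Allele.R, 1 - x)] if a is Allele.WT else [(a, Fraction(1))]
        for a in parent.alleles
    ]
    for ma, pm in branches[0]:
        for pa, pp in branches[1]:
            g = Genotype(ma, pa)
            outcomes[g] = outcomes.get(g, Fraction(0)) + pm * pp
    return GenotypeDistribution(outcomes)


def gametes(germline: Genotype) -> GameteDistribution:
    """Mendelian segregation: each allele transmitted with probability 1/2.

    The R* provenance label resets at meiosis — an R* allele is transmitted
    as R, since the two are the same mutated target site.
    """
    acc: dict[Allele, Fraction] = {}
    for a in germline:
        if a is Allele.RSTAR:
            a = Allele.R
        acc[a] = acc.get(a, Fraction(0)) + Fraction(1, 2)
    return GameteDistribution(acc)


def maternal_zygotic_effect(
    zygote: Genotype, mother_has_drive: bool, y
) -> GenotypeDistribution:
    """Zygotic mutation by maternally deposited Cas9/gRNA.

    If the mother carries a drive cassette, each WT allele of the zygote is
    independently mutated to R* with probability ``y``; GD, R and R* alleles
    are unaffected.  A mother without the drive deposits nothing (identity).
    """
    y = as_probability(y, "y")
    if not mother_has_drive:
        return GenotypeDistribution({zygote: Fraction(1)})
    outcomes: dict[Genotype, Fraction] = {}
    branches = [
        [(Allele.WT, 1 - y), (Allele.RSTAR, y)] if a is Allele.WT
        else [(a, Fraction(1))]
        for a in zygote.alleles
    ]
    for ma, pm in branches[0]:
        for pa, pp in branches[1]:
            g = Genotype(ma, pa)
            outcomes[g] = outcomes.get(g, Fraction(0)) + pm * pp
    return GenotypeDistribution(outcomes)


def gamete_pool(parent: Genotype, x) -> GameteDistribution:
    """Marginal gamete distribution of a parent after germline conversion."""
    acc: dict[Allele, Fraction] = {}
    for germ, pg in germline_convert(parent, x).items():
        for a, pa in gametes(germ).items():
            acc[a] = acc.get(a, Fraction(0)) + pg * pa
    return GameteDistribution(acc)


def cross(
    mother: Genotype,
    father: Genotype,
    params: DriveParams,
    maternal_effect: bool = True,
    fitness: Mapping[Genotype, Fraction] | None = None,
) -> GenotypeDistribution:
    """Exact offspring genotype distribution of a single cross.

    Composes germline conversion in both parents, Mendelian gametes, zygote
    formation, and the zygotic maternal-effect operator (active iff the
    mother carries a drive allele and ``maternal_effect`` is True).

    ``fitness`` optionally assigns a relative viability to each offspring
    genotype (unordered); the distribution is reweighted and renormalised.
    Defaults to neutrality.
    """
    mother_pool = gamete_pool(mother, params.x)
    father_pool = gamete_pool(father, params.x)
    apply_me = maternal_effect and mother.has_drive

    acc: dict[Genotype, Fraction] = {}
    for ma, pm in mother_pool.items():
        for pa, pp in father_pool.items():
            zygote = Genotype(maternal=ma, paternal=pa)
            w = pm * pp
            if apply_me:
                for g, pz in maternal_zygotic_effect(zygote, True, params.y).items():
                    acc[g] = acc.get(g, Fraction(0)) + w * pz
            else:
                acc[zygote] = acc.get(zygote, Fraction(0)) + w

    if fitness is not None:
        weighted = {
            g: p * Fraction(fitness.get(g.canonical(), 1))
            for g, p in acc.items()
        }
        total = sum(weighted.values(), Fraction(0))
        if total == 0:
            raise ValueError("all offspring genotypes have zero fitness")
        acc = {g: p / total for g, p in weighted.items()}
    return GenotypeDistribution(acc)


@lru_cache(maxsize=4096)
def cross_cached(
    mother: Genotype, father: Genotype, params: DriveParams, maternal_effect: bool
) -> GenotypeDistribution:
    """Memoised neutral :func:`cross` (parents taken as unordered genotypes)."""
    return cross(mother.canonical(), father.canonical(), params, maternal_effect)
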