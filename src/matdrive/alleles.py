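"""Allele and genotype algebra for a single CRISPR-targeted locus.

The locus has four allele states:

* ``WT`` — intact wild-type target site, cleavable by Cas9/gRNA.
* ``GD`` — the homing gene-drive cassette (Cas9 + gRNA) inserted at the
  locus; drives its own copying into a WT partner allele via HDR.
* ``R`` — drive-resistant allele created in the germline when homing fails
  and the break is repaired by NHEJ (target site destroyed, no cargo).
* ``R*`` — drive-resistant allele created in the zygote by maternally
  deposited Cas9/gRNA (the dominant maternal effect).

``R`` and ``R*`` are genetically identical mutated target sites; the star is
a bookkeeping label for the generation in which the mutation arose, and it
resets to ``R`` at meiosis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator


class Allele(enum.Enum):
    """One of the four locus states."""

    GD = "GD"
    R = "R"
    RSTAR = "R*"
    WT = "WT"

    @property
    def resistant(self) -> bool:
        """True for a mutated, uncleavable target site (R or R*)."""
        return self in (Allele.R, Allele.RSTAR)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


# Canonical ordering used for unordered genotype labels ("GD/WT", "R/R*").
_SORT_KEY = {Allele.GD: 0, Allele.R: 1, Allele.RSTAR: 2, Allele.WT: 3}

_TOKENS = {
    "WT": Allele.WT,
    "+": Allele.WT,
    "GD": Allele.GD,
    "R": Allele.R,
    "RSTAR": Allele.RSTAR,
    "R*": Allele.RSTAR,
}


def parse_allele(token: str) -> Allele:
    """Parse an allele token (``WT``/``+``, ``GD``, ``R``, ``RSTAR``/``R*``)."""
    try:
        return _TOKENS[token.strip().upper().replace("R*", "R*")]
    except KeyError:
        raise ValueError(
            f"unknown allele token {token!r}; expected one of WT, GD, R, RSTAR"
        ) from None


@dataclass(frozen=True)
class Genotype:
    """An ordered diploid genotype at the drive locus.

    Parental origin is preserved (``maternal`` vs ``paternal``) because the
    zygotic maternal-effect operator acts on specific alleles.  Equality for
    reporting collapses to the unordered pair via :meth:`canonical` /
    :meth:`label`.
    """

    maternal: Allele
    paternal: Allele

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.maternal, self.paternal)

    @property
    def has_drive(self) -> bool:
        """Whether this individual carries at least one drive cassette."""
        return Allele.GD in self.alleles

    def canonical(self) -> "Genotype":
        """The unordered representative (alleles in canonical display order)."""
        a, b = sorted(self.alleles, key=_SORT_KEY.__getitem__)
        return Genotype(a, b)

    @property
    def label(self) -> str:
        """Unordered display label, e.g. ``GD/WT``, ``R/R*``."""
        a, b = self.canonical().alleles
        return f"{a}/{b}"

    def __iter__(self) -> Iterator[Allele]:
        return iter(self.alleles)

    def __str__(self) -> str:
        return self.label


def parse_genotype(text: str) -> Genotype:
    """Parse ``"GD/WT"``-style genotype strings.

    The first token is taken as the maternal allele when provenance matters;
    for unordered uses the order is irrelevant.
    """
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"genotype {text!r} must be two '/'-separated alleles")
    return Genotype(parse_allele(parts[0]), parse_allele(parts[1]))


#: All ten unordered diploid genotypes, in canonical order.
ALL_GENOTYPES: tuple[Genotype, ...] = tuple(
    Genotype(a, b)
    for i, a in enumerate(sorted(Allele, key=_SORT_KEY.__getitem__))
    for b in sorted(Allele, key=_SORT_KEY.__getitem__)[i:]
)

WILDTYPE = Genotype(Allele.WT, Allele.WT)
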