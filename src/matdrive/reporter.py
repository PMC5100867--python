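"""Dual-reporter readout of the targeted GAL4 locus.

In the experimental system the drive target is a GAL4 transgene.  Each
allele copy is in one of three states: intact GAL4, NHEJ-disrupted GAL4
(dGAL4), or a QF2 knock-in created by HDR.  Two orthogonal binary
expression systems act as reporters: intact GAL4 drives a UAS-GFP reporter,
QF2 drives a QUAS-lacZ reporter, and dGAL4 drives neither — a three-state
readout of editing outcomes, per cell (somatic mosaicism) or per transmitted
allele (progeny classification).

Reporter state equals genetic state here; perdurance and expression
thresholds are ignored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from collections.abc import Iterable

__all__ = [
    "LocusState",
    "ReporterReadout",
    "SomaticRates",
    "readout",
    "classify_progeny_class",
    "expected_somatic_counts",
    "PROGENY_CLASSES",
]


class LocusState(enum.Enum):
    GAL4_INTACT = "GAL4"
    DGAL4 = "dGAL4"
    QF2_KNOCKIN = "QF2"


#: Serialised progeny-class names used in count tables.
PROGENY_CLASSES = ("GAL4+", "dGAL4", "QF2+")

_CLASS_OF = {
    LocusState.GAL4_INTACT: "GAL4+",
    LocusState.DGAL4: "dGAL4",
    LocusState.QF2_KNOCKIN: "QF2+",
}


@dataclass(frozen=True)
class ReporterReadout:
    """Which reporters are on in a cell/animal."""

    gfp_on: bool
    lacz_on: bool


def readout(states: Iterable[LocusState]) -> ReporterReadout:
    """Reporter readout given the locus states of all GAL4-bearing alleles.

    GFP is on iff any allele retains intact GAL4; lacZ is on iff any allele
    carries the QF2 knock-in; dGAL4 alone lights neither.
    """
    states = set(states)
    if not states:
        raise ValueError("readout requires at least one locus state")
    return ReporterReadout(
        gfp_on=LocusState.GAL4_INTACT in states,
        lacz_on=LocusState.QF2_KNOCKIN in states,
    )


def classify_progeny_class(locus: LocusState) -> str:
    """Class of an offspring carrying a single transmitted GAL4-locus allele."""
    return _CLASS_OF[locus]


@dataclass(frozen=True)
class SomaticRates:
    """Per-cell editing outcome probabilities in a tissue of ``n_cells``.

    ``p_intact + p_hdr + p_nhej`` must equal 1; the default tissue size of
    100,000 matches the neuron count of an adult fly brain.
    """

    p_intact: float
    p_hdr: float
    p_nhej: float
    n_cells: int = 100_000

    def __post_init__(self) -> None:
        for name in ("p_intact", "p_hdr", "p_nhej"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.p_intact + self.p_hdr + self.p_nhej - 1) > 1e-9:
            raise ValueError("p_intact + p_hdr + p_nhej must equal 1")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


def expected_somatic_counts(rates: SomaticRates) -> tuple[float, float]:
    """Expected (GFP+, lacZ+) labelled-cell counts under per-cell independence."""
    return rates.p_intact * rates.n_cells, rates.p_hdr * rates.n_cells
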