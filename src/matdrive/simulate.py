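"""Seeded synthetic data with the statistical structure of the experiments.

Three generators:

* germline progeny-class counts — per cross, n progeny fall into
  (GAL4+, dGAL4, QF2+) with trinomial probabilities (1-d, d(1-h), d*h);
* per-brain labelled-cell counts — binomial draws over ~100,000 neurons,
  with an optional beta-binomial overdispersion knob for clonal correlation
  among cells edited in the early embryo;
* drive cohorts — finite samples of individuals per generation from the
  exact pedigree/population genotype distributions.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import MatingScheme, PopulationState, propagate, release_state
from .model import DriveParams
from .reporter import SomaticRates

__all__ = [
    "GermlineCross",
    "GermlineSimSpec",
    "SomaticSimSpec",
    "simulate_germline_counts",
    "simulate_brain_counts",
    "simulate_drive_cohort",
    "default_germline_spec",
]


@dataclass(frozen=True)
class GermlineCross:
    """True (d, h) and progeny number for one simulated cross."""

    cross_id: str
    d: float
    h: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.d <= 1 and 0 <= self.h <= 1):
            raise ValueError("d and h must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class GermlineSimSpec:
    crosses: tuple[GermlineCross, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "crosses", tuple(self.crosses))


@dataclass(frozen=True)
class SomaticSimSpec:
    """Per-brain count simulation: rates, number of brains, overdispersion.

    ``rho`` is the beta-binomial intra-class correlation; 0 gives pure
    per-cell-independent binomial counts.
    """

    rates: SomaticRates
    n_brains: int
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_brains < 1:
            raise ValueError("n_brains must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


def default_germline_spec(seed: int = 0) -> GermlineSimSpec:
    """Four-cross fixture mirroring the germline-transmission experiment.

    The crosses correspond to F1 fathers carrying (1) both Cas9 and gRNA
    transgenes, (2) Cas9 only, (3) gRNA only, (4) neither component (all
    from drive-component-bearing mothers).  Disruption rates are set near
    the observed 98.2/92/97/87.2%; the HDR fraction is nonzero only where a
    donor cassette is present, at the ~10% HDR-vs-NHEJ scale reported for
    the donor's genomic site.  Synthetic, inspired by — not equal to — the
    measured data.
    """
    return GermlineSimSpec(
        crosses=(
            GermlineCross("both_components", d=0.982, h=0.10, n=164),
            GermlineCross("cas9_only", d=0.92, h=0.0, n=200),
            GermlineCross("grna_only", d=0.97, h=0.10, n=200),
            GermlineCross("no_components", d=0.872, h=0.0, n=413),
        ),
        seed=seed,
    )


def simulate_germline_counts(spec: GermlineSimSpec) -> pd.DataFrame:
    """Trinomial progeny-class counts per cross (columns: cross_id, GAL4plus,
    dGAL4, QF2plus)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in spec.crosses:
        probs = [1 - c.d, c.d * (1 - c.h), c.d * c.h]
        gal4, dgal4, qf2 = rng.multinomial(c.n, probs)
        rows.append({"cross_id": c.cross_id, "GAL4plus": int(gal4),
                     "dGAL4": int(dgal4), "QF2plus": int(qf2)})
    return pd.DataFrame(rows)


def _beta_binomial(rng: np.random.Generator, n: int, p: float, rho: float,
                   size: int) -> np.ndarray:
    if p in (0.0, 1.0) or rho == 0.0:
        return rng.binomial(n, p, size=size)
    # mean-matched beta mixing: a+b = (1-rho)/rho gives ICC rho
    conc = (1 - rho) / rho
    ps = rng.beta(p * conc, (1 - p) * conc, size=size)
    return rng.binomial(n, ps)


def simulate_brain_counts(spec: SomaticSimSpec) -> pd.DataFrame:
    """Per-brain (GFP+, lacZ+) labelled-cell counts.

    Columns: brain_id, gfp_cells (intact GAL4), lacz_cells (QF2 knock-in).
    With rho > 0 each brain's per-cell rate is beta-distributed around the
    specified mean, inflating between-brain variance above binomial.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.rates
    gfp = _beta_binomial(rng, r.n_cells, r.p_intact, spec.rho, spec.n_brains)
    lacz = _beta_binomial(rng, r.n_cells, r.p_hdr, spec.rho, spec.n_brains)
    return pd.DataFrame({
        "brain_id": [f"brain_{i + 1}" for i in range(spec.n_brains)],
        "gfp_cells": gfp.astype(int),
        "lacz_cells": lacz.astype(int),
    })


def simulate_drive_cohort(
    params: DriveParams,
    scheme: MatingScheme,
    n_per_generation: int,
    n_generations: int,
    seed: int,
    initial: PopulationState | None = None,
    maternal_effect: bool = True,
) -> pd.DataFrame:
    """Finite cohorts sampled from the exact per-generation genotype
    distributions (columns: generation, genotype, count).

    Each generation's cohort is an independent multinomial draw of
    ``n_per_generation`` individuals from the deterministic trajectory's
    exact genotype distribution.
    """
    if n_per_generation < 1:
        raise ValueError("n_per_generation must be >= 1")
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = release_state(scheme)
    traj = propagate(initial, scheme, params, n_generations, maternal_effect)
    rows = []
    for state in traj.states:
        gf = state.genotype_frequencies()
        labels = [g.label for g in gf]
        counts = rng.multinomial(n_per_generation, [float(p) for p in gf.values()])
        for label, count in zip(labels, counts):
            rows.append({"generation": state.generation, "genotype": label,
                         "count": int(count)})
    return pd.DataFrame(rows)
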