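"""Independent Monte-Carlo simulator of the single-cross mechanism.

Implements the same mechanistic steps as the exact enumerator — germline
homing, Mendelian transmission, zygotic maternal effect — but by direct
per-offspring sampling with numpy, sharing no code with the rational
enumeration.  It exists to cross-validate the enumerator: at large draw
counts the empirical genotype frequencies must agree with the exact
probabilities to within sampling error.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .alleles import Allele, Genotype
from .model import DriveParams

__all__ = ["simulate_cross", "mc_vs_exact"]

# integer codes for the vectorised sampler
_WT, _GD, _R, _RSTAR = 0, 1, 2, 3
_CODE = {Allele.WT: _WT, Allele.GD: _GD, Allele.R: _R, Allele.RSTAR: _RSTAR}
_ALLELE = {v: k for k, v in _CODE.items()}


def _germline_and_transmit(
    genotype: Genotype, x: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Transmitted allele codes for n independent parent individuals."""
    a = np.full(n, _CODE[genotype.maternal])
    b = np.full(n, _CODE[genotype.paternal])
    if genotype.has_drive:
        # homing: each WT allele converted to GD w.p. x, else to R
        for arr in (a, b):
            wt = arr == _WT
            conv = rng.random(n) < x
            arr[wt & conv] = _GD
            arr[wt & ~conv] = _R
    pick_b = rng.random(n) < 0.5
    out = np.where(pick_b, b, a)
    out[out == _RSTAR] = _R  # provenance label resets at meiosis
    return out


def simulate_cross(
    mother: Genotype,
    father: Genotype,
    params: DriveParams,
    n: int,
    seed: int | np.random.Generator,
    maternal_effect: bool = True,
) -> dict[str, int]:
    """Sample n offspring of a cross; returns counts by unordered genotype label.

    Each offspring is produced by an independent realisation of the parents'
    germlines (equivalently, each offspring comes from a fresh parent pair —
    the per-offspring marginal is identical).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y = float(params.x), float(params.y)
    mat = _germline_and_transmit(mother, x, n, rng)
    pat = _germline_and_transmit(father, x, n, rng)
    if maternal_effect and mother.has_drive:
        for arr in (mat, pat):
            hit = (arr == _WT) & (rng.random(n) < y)
            arr[hit] = _RSTAR
    # count unordered allele pairs without a per-offspring Python loop
    key = 4 * np.minimum(mat, pat) + np.maximum(mat, pat)
    counts = np.bincount(key, minlength=16)
    out: Counter[str] = Counter()
    for k in np.nonzero(counts)[0]:
        label = Genotype(_ALLELE[int(k) // 4], _ALLELE[int(k) % 4]).label
        out[label] += int(counts[k])
    return dict(out)


def mc_vs_exact(
    mother: Genotype,
    father: Genotype,
    params: DriveParams,
    n: int,
    seed: int | np.random.Generator,
    maternal_effect: bool = True,
) -> list[dict]:
    """Compare Monte-Carlo frequencies with exact enumeration per genotype.

    Returns one record per genotype occurring in either route, with the
    exact probability, the empirical frequency, and the discrepancy in
    units of the binomial standard error sqrt(p(1-p)/n) (infinite when the
    exact probability is 0 or 1 but the observation disagrees).
    """
    from .model import cross  # local import keeps the two routes visibly separate

    exact = {g.label: float(p) for g, p in
             cross(mother, father, params, maternal_effect).unordered().items()}
    counts = simulate_cross(mother, father, params, n, seed, maternal_effect)
    records = []
    for label in sorted(set(exact) | set(counts)):
        p = exact.get(label, 0.0)
        obs = counts.get(label, 0) / n
        se = np.sqrt(p * (1 - p) / n)
        z = abs(obs - p) / se if se > 0 else (0.0 if obs == p else np.inf)
        records.append({"genotype": label, "exact": p, "observed": obs,
                        "se": se, "z": z})
    return records
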