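"""Estimation of editing rates from trinomial progeny-class counts.

Each cross contributes counts over the three progeny classes (GAL4+,
dGAL4, QF2+).  Two derived proportions are estimated:

* ``d`` — total disruption rate, P(allele not intact) = (dGAL4 + QF2+)/n;
* ``h`` — HDR fraction among disrupted alleles, QF2+/(dGAL4 + QF2+).

Point estimates are the MLEs; intervals are Wilson score intervals (chosen
over Wald because observed rates sit near 1, where Wald degenerates).
When a cross's progeny all lack genomic editing components but the mother
carried them, ``d`` estimates the germline maternal-effect mutation rate —
the quantity the drive model calls ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import confint_proportions_2indep, proportion_confint

__all__ = [
    "TrinomialRates",
    "RateDifference",
    "fit_trinomial",
    "fit_counts",
    "estimate_maternal_rate",
    "compare_rates",
]

_COUNT_COLUMNS = ("GAL4plus", "dGAL4", "QF2plus")


@dataclass(frozen=True)
class TrinomialRates:
    """Estimates for one cross: disruption rate d and HDR fraction h."""

    d: float
    h: float
    ci_d: tuple[float, float]
    ci_h: tuple[float, float]
    n: int
    n_disrupted: int
    level: float = 0.95
    h_degenerate: bool = False
    cross_id: str | None = None


@dataclass(frozen=True)
class RateDifference:
    """Difference of two disruption rates with a Newcombe score interval."""

    diff: float
    ci: tuple[float, float]
    level: float = 0.95


def _wilson(count: int, nobs: int, alpha: float) -> tuple[float, float]:
    """Wilson score interval with exact boundary behaviour.

    The closed-form Wilson bounds are exactly 0 at zero successes and
    exactly 1 at zero failures; clamp the floating-point noise the library
    evaluation leaves there (e.g. 1.7e-18 instead of 0).
    """
    low, high = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    low = 0.0 if count == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if count == nobs else min(max(float(high), 0.0), 1.0)
    return low, high


def _counts_from(row) -> tuple[int, int, int]:
    if isinstance(row, (pd.Series, dict)):
        vals = [row[c] for c in _COUNT_COLUMNS]
    else:
        vals = list(row)
    out = []
    for c, v in zip(_COUNT_COLUMNS, vals):
        iv = int(v)
        if iv != v or iv < 0:
            raise ValueError(f"{c} must be a nonnegative integer, got {v!r}")
        out.append(iv)
    return tuple(out)


def fit_trinomial(row, level: float = 0.95) -> TrinomialRates:
    """MLE and Wilson intervals for (d, h) from one cross's class counts.

    ``row`` is a mapping/Series with keys GAL4plus, dGAL4, QF2plus, or a
    plain (GAL4+, dGAL4, QF2+) triple.  With zero disrupted progeny, h is
    undefined; it is reported as 0 with ``h_degenerate=True`` and a vacuous
    [0, 1] interval.
    """
    gal4, dgal4, qf2 = _counts_from(row)
    n = gal4 + dgal4 + qf2
    if n < 1:
        raise ValueError("cannot fit a cross with zero total progeny")
    disrupted = dgal4 + qf2
    alpha = 1 - level
    d = disrupted / n
    ci_d = _wilson(disrupted, n, alpha)
    if disrupted == 0:
        h, ci_h, degenerate = 0.0, (0.0, 1.0), True
    else:
        h = qf2 / disrupted
        ci_h = _wilson(qf2, disrupted, alpha)
        degenerate = False
    cid = row.get("cross_id") if isinstance(row, (pd.Series, dict)) else None
    return TrinomialRates(
        d=d, h=h, ci_d=ci_d, ci_h=ci_h, n=n, n_disrupted=disrupted,
        level=level, h_degenerate=degenerate,
        cross_id=None if cid is None else str(cid),
    )


def fit_counts(table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Fit every row of a count table; returns one estimate row per cross."""
    if table.empty:
        raise ValueError("count table has no rows")
    rows = []
    for _, row in table.iterrows():
        fit = fit_trinomial(row, level=level)
        rows.append({
            "cross_id": fit.cross_id, "n": fit.n,
            "d": fit.d, "d_low": fit.ci_d[0], "d_high": fit.ci_d[1],
            "h": fit.h, "h_low": fit.ci_h[0], "h_high": fit.ci_h[1],
            "h_degenerate": fit.h_degenerate,
        })
    return pd.DataFrame(rows)


def estimate_maternal_rate(no_component_row, level: float = 0.95) -> TrinomialRates:
    """Maternal-effect germline mutation rate from the no-genomic-components cross.

    The input row must come from progeny that carry neither Cas9 nor gRNA
    transgenes while their mother carried both: any disruption then reflects
    maternally deposited editing activity in the germline precursors, so the
    disruption rate ``d`` estimates the drive model's parameter ``y``.
    """
    return fit_trinomial(no_component_row, level=level)


def compare_rates(row_a, row_b, level: float = 0.95) -> RateDifference:
    """Difference of disruption rates d_a - d_b with a Newcombe score interval.

    An interval, not a test verdict: the experiments motivating this
    comparison report proportions without formal hypothesis tests.
    """
    fa, fb = fit_trinomial(row_a, level=level), fit_trinomial(row_b, level=level)
    low, high = confint_proportions_2indep(
        fa.n_disrupted, fa.n, fb.n_disrupted, fb.n,
        method="newcomb", compare="diff", alpha=1 - level,
    )
    return RateDifference(diff=fa.d - fb.d, ci=(float(low), float(high)), level=level)
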