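"""Conversions between Cohen's d and Hedges' g, and CI-derived standard errors.

Hedges' g is Cohen's d shrunk by the small-sample bias-correction factor

    J(N) = 1 - 3 / (4 N - 9),        N = n1 + n2,

so ``g = d * J`` and the inverse ``d = g / J`` is exact.  The factor depends
only on the combined sample size, so a record reporting a single total N can
be corrected without knowing the group split.
"""

from __future__ import annotations

import dataclasses
import warnings

from scipy import stats

from .records import EffectRecord, ESMetric

__all__ = [
    "correction_factor",
    "d_to_g",
    "g_to_d",
    "harmonize_to_d",
    "harmonize_all",
    "se_from_ci",
]


def correction_factor(n_total: int) -> float:
    """Small-sample correction J = 1 - 3/(4N - 9); strictly increasing in N."""
    if n_total < 3:
        raise ValueError(f"combined sample size must be >= 3, got {n_total}")
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def _n_total(n1: int, n2: int | None) -> int:
    # n2=None means n1 already holds the combined sample size
    return int(n1) if n2 is None else int(n1) + int(n2)


def d_to_g(d: float, n1: int, n2: int | None = None) -> float:
    """Convert Cohen's d to Hedges' g.  Pass n2=None if n1 is the total N."""
    return d * correction_factor(_n_total(n1, n2))


def g_to_d(g: float, n1: int, n2: int | None = None) -> float:
    """Exact algebraic inverse of :func:`d_to_g`."""
    factor = correction_factor(_n_total(n1, n2))
    if factor == 0.0:  # N = 3 degenerates: the correction annihilates g
        raise ValueError("correction factor is zero at a combined sample of 3")
    return g / factor


def harmonize_to_d(record: EffectRecord) -> EffectRecord:
    """Express a record on the Cohen's d scale where the sample sizes allow.

    Hedges' g records with both group sizes are divided by the correction
    factor (confidence bounds rescaled by the same factor) and relabelled
    ``cohens_d``.  A g record lacking a sample size is passed through with
    ``unconverted_g=True`` so downstream pooling can identify it; Cohen's d
    records pass through unchanged.
    """
    if record.es_metric is ESMetric.COHENS_D:
        return record
    if record.n_total is None:
        if record.unconverted_g:
            return record
        return dataclasses.replace(record, unconverted_g=True)
    factor = correction_factor(record.n_total)
    return dataclasses.replace(
        record,
        es_value=record.es_value / factor,
        ci_lower=None if record.ci_lower is None else record.ci_lower / factor,
        ci_upper=None if record.ci_upper is None else record.ci_upper / factor,
        es_metric=ESMetric.COHENS_D,
        unconverted_g=False,
    )


def harmonize_all(records) -> list[EffectRecord]:
    """Element-wise :func:`harmonize_to_d`, order preserved."""
    return [harmonize_to_d(r) for r in records]


def se_from_ci(
    ci_lower: float,
    ci_upper: float,
    level: float = 0.95,
    *,
    estimate: float | None = None,
    asymmetry_tol: float = 1e-8,
) -> float:
    """Standard error implied by a symmetric normal-theory interval.

    Returns ``(ci_upper - ci_lower) / (2 z)`` with z the standard-normal
    quantile at (1+level)/2 (1.959964 for 95%).  If ``estimate`` is supplied
    and not at the interval midpoint, the interval is asymmetric: half the
    full width is still used, with a warning.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if ci_upper < ci_lower:
        raise ValueError(f"inverted interval ({ci_lower}, {ci_upper})")
    width = ci_upper - ci_lower
    if estimate is not None:
        mid = 0.5 * (ci_lower + ci_upper)
        if abs(estimate - mid) > asymmetry_tol * max(1.0, width):
            warnings.warn(
                f"asymmetric interval around {estimate}: using half-width",
                stacklevel=2,
            )
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return width / (2.0 * z)
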