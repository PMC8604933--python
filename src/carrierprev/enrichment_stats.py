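"""Allele-frequency enrichment against a reference population.

Each cohort variant is compared with a large reference population
(gnomAD-NFE style: an allele frequency plus a number of sequenced
individuals) through a 2x2 table of alternate/reference allele counts.
Enrichment is assessed with the one-sided Fisher exact test (alternative:
cohort enriched) and the odds ratio reported is the conditional maximum
likelihood estimate (cMLE) under the Fisher noncentral hypergeometric
distribution — the convention of R's ``fisher.test`` — alongside the plain
sample odds ratio as a diagnostic.

Reference alternate-allele counts are reconstructed from the published
frequency by nearest-integer rounding of ``af * 2N``; exact counts are
preferred when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

from .annotation_filter import AnnotatedVariant

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "allele_frequency",
    "reconstruct_reference_counts",
    "fisher_one_sided",
    "odds_ratio_cmle",
    "sample_odds_ratio",
    "enrich_all",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Alt/ref allele counts in the cohort (a, b) and the reference (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            val = getattr(self, name)
            if not (isinstance(val, (int, np.integer)) and val >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {val!r}")

    @property
    def cohort_an(self) -> int:
        return self.a + self.b

    @property
    def reference_an(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable2x2":
        """Matrix transpose; leaves the odds ratio unchanged."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def allele_swapped(self) -> "ContingencyTable2x2":
        """Interchange alt and ref columns; inverts the odds ratio."""
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-variant enrichment summary; ``error`` flags a failed row."""

    variant_id: str
    cohort_af: float
    reference_af: float
    p_one_sided: Optional[float]
    or_cmle: Optional[float]
    or_sample: Optional[float]  # None when undefined (zero in b*c)
    error: Optional[str] = None


def allele_frequency(ac: int, an: int) -> float:
    """Alternate-allele frequency ``ac / an`` (two alleles per diploid)."""
    if an <= 0:
        raise ValueError(f"an must be positive, got {an}")
    if not 0 <= ac <= an:
        raise ValueError(f"require 0 <= ac <= an, got ac={ac}, an={an}")
    return ac / an


def reconstruct_reference_counts(af: float, n_individuals: int) -> tuple[int, int]:
    """Integer (ac, an) for a reference population reported only as a frequency.

    ``an = 2 * n_individuals``; ``ac`` is ``af * an`` rounded half away from
    zero, so the reconstruction round-trips with the printed frequency at
    its reported precision.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"af must lie in [0,1], got {af}")
    an = 2 * int(n_individuals)
    ac = int(math.floor(af * an + 0.5))
    return ac, an


def _support(t: ContingencyTable2x2) -> tuple[int, int]:
    """Attainable range of the cohort-alt cell given the table margins."""
    n_draws, n_success = t.a + t.b, t.a + t.c
    lo = max(0, n_draws + n_success - t.total)
    hi = min(n_draws, n_success)
    return lo, hi


def fisher_one_sided(t: ContingencyTable2x2) -> float:
    """Upper-tail hypergeometric probability P(X >= a) given the margins.

    One-sided Fisher exact test with alternative "cohort enriched".
    """
    if t.total == 0:
        raise ValueError("all-zero table")
    return float(hypergeom.sf(t.a - 1, t.total, t.a + t.c, t.a + t.b))


def _conditional_mean(log_psi: float, xs: np.ndarray, log_w: np.ndarray) -> float:
    """E[X | margins] under the noncentral hypergeometric with log-odds log_psi."""
    log_terms = log_w + xs * log_psi
    log_norm = logsumexp(log_terms)
    return float(np.exp(logsumexp(log_terms, b=xs) - log_norm))


def odds_ratio_cmle(t: ContingencyTable2x2, rtol: float = 1e-9) -> float:
    """Conditional MLE of the odds ratio for a 2x2 table.

    Maximises the Fisher noncentral hypergeometric likelihood of the
    observed cohort-alt count given the table margins, i.e. solves
    ``E_psi[X | margins] = a`` by monotone root-finding on ``log psi``.
    Returns 0 when ``a`` sits at the minimum attainable value and ``inf``
    at the maximum (the likelihood is then maximised at the boundary).
    """
    if t.a + t.c == 0 or t.a + t.b == 0:
        raise ValueError("degenerate margins: no alternate alleles or no cohort alleles")
    lo, hi = _support(t)
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf

    xs = np.arange(lo, hi + 1, dtype=float)
    n_draws, n_success = t.a + t.b, t.a + t.c
    log_w = (
        gammaln(n_success + 1) - gammaln(xs + 1) - gammaln(n_success - xs + 1)
        + gammaln(t.total - n_success + 1)
        - gammaln(n_draws - xs + 1)
        - gammaln(t.total - n_success - n_draws + xs + 1)
    )

    def f(log_psi: float) -> float:
        return _conditional_mean(log_psi, xs, log_w) - t.a

    # expand a bracket around 0; E[X] is strictly increasing in log psi
    left, right = -1.0, 1.0
    while f(left) > 0:
        left *= 2.0
    while f(right) < 0:
        right *= 2.0
    log_psi = brentq(f, left, right, xtol=1e-12, rtol=rtol)
    return float(math.exp(log_psi))


def sample_odds_ratio(t: ContingencyTable2x2) -> Optional[float]:
    """Sample odds ratio (a*d)/(b*c); ``None`` when undefined (b*c = 0)."""
    if t.b * t.c == 0:
        return None
    return (t.a * t.d) / (t.b * t.c)


def enrich_all(
    variants: Iterable[AnnotatedVariant],
    reference_n_individuals: Optional[int] = None,
) -> list[EnrichmentResult]:
    """Enrichment statistics for every variant, sorted by ascending p.

    Each variant must carry cohort counts plus ``reference_af`` and a
    reference population size (per-variant ``reference_n_individuals`` or
    the shared fallback argument).  Per-variant failures become flagged
    rows; the batch never aborts.
    """
    results: list[EnrichmentResult] = []
    for v in variants:
        try:
            n_ref = v.reference_n_individuals or reference_n_individuals
            if v.reference_af is None or not n_ref:
                raise ValueError("missing reference_af or reference_n_individuals")
            ref_ac, ref_an = reconstruct_reference_counts(v.reference_af, n_ref)
            t = ContingencyTable2x2(v.cohort_ac, v.cohort_an - v.cohort_ac,
                                    ref_ac, ref_an - ref_ac)
            results.append(
                EnrichmentResult(
                    variant_id=v.variant_id,
                    cohort_af=v.cohort_af,
                    reference_af=v.reference_af,
                    p_one_sided=fisher_one_sided(t),
                    or_cmle=odds_ratio_cmle(t),
                    or_sample=sample_odds_ratio(t),
                )
            )
        except (ValueError, ZeroDivisionError) as exc:
            results.append(
                EnrichmentResult(
                    variant_id=v.variant_id,
                    cohort_af=v.cohort_af if v.cohort_an else float("nan"),
                    reference_af=v.reference_af if v.reference_af is not None else float("nan"),
                    p_one_sided=None,
                    or_cmle=None,
                    or_sample=None,
                    error=str(exc),
                )
            )
    results.sort(key=lambda r: (r.p_one_sided is None, r.p_one_sided))
    return results
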