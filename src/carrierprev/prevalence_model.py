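"""Hardy-Weinberg projection of recessive-disease prevalence.

The cumulative frequency q of the pathogenic allele class (all pathogenic
alleles at the locus pooled) gives, under Hardy-Weinberg equilibrium
(p^2 + 2pq + q^2 = 1, random mating) and complete penetrance, an expected
affected birth incidence of q^2.  Scaling by annual births yields the
expected number of new cases per year, and q^2 * 1e5 the prevalence per
100,000 births.  Compound heterozygotes of the pooled allele class are
already counted by q^2; no separate term is added.

Uncertainty comes from the binomial sampling of alleles in the cohort:
q receives an exact Clopper-Pearson interval whose endpoints are squared
and scaled to a prevalence interval.

Reported numbers are rounded half away from zero (q^2 to 4 significant
figures, cases/year and per-100k prevalences to 2 decimals); full
precision is retained internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from scipy.stats import beta

from .annotation_filter import AnnotatedVariant

__all__ = [
    "PrevalenceEstimate",
    "ScenarioPrevalence",
    "ASSUMPTIONS",
    "cumulative_pathogenic_frequency",
    "hwe_prevalence",
    "scenario_prevalence",
    "prevalence_interval",
    "pooled_mean_prevalence",
    "round_half_up",
]

#: assumptions surfaced verbatim in every report
ASSUMPTIONS = (
    "Hardy-Weinberg equilibrium (random mating, panmixia)",
    "complete penetrance of the biallelic genotype",
    "pooled pathogenic allele class: q^2 counts all homozygous and compound-"
    "heterozygous combinations of pathogenic alleles",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Hardy-Weinberg prevalence projection from the pooled allele frequency."""

    q: float
    births_per_year: int
    q_ci: Optional[tuple[float, float]] = None
    level: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0,1], got {self.q}")
        if self.births_per_year <= 0:
            raise ValueError("births_per_year must be positive")
        if self.q_ci is not None and not self.q_ci[0] <= self.q_ci[1]:
            raise ValueError("q_ci bounds out of order")

    @property
    def p(self) -> float:
        return 1.0 - self.q

    @property
    def q_squared(self) -> float:
        return self.q * self.q

    @property
    def expected_cases_per_year(self) -> float:
        return self.q_squared * self.births_per_year

    @property
    def prevalence_per_100k(self) -> float:
        return self.q_squared * 1e5

    @property
    def prevalence_ci_per_100k(self) -> Optional[tuple[float, float]]:
        if self.q_ci is None:
            return None
        lo, hi = self.q_ci
        return (lo * lo * 1e5, hi * hi * 1e5)

    def report(self) -> dict:
        """Printed-precision rendering alongside the full-precision values."""
        out = {
            "q": self.q,
            "p": self.p,
            "q_squared": self.q_squared,
            "q_squared_4sf": float(f"{self.q_squared:.4g}"),
            "births_per_year": self.births_per_year,
            "expected_cases_per_year": self.expected_cases_per_year,
            "expected_cases_per_year_2dp": round_half_up(self.expected_cases_per_year),
            "prevalence_per_100k": self.prevalence_per_100k,
            "prevalence_per_100k_2dp": round_half_up(self.prevalence_per_100k),
            "assumptions": list(ASSUMPTIONS),
        }
        if self.q_ci is not None:
            out["level"] = self.level
            out["q_ci"] = list(self.q_ci)
            out["prevalence_ci_per_100k"] = list(self.prevalence_ci_per_100k)
        return out


@dataclass(frozen=True)
class ScenarioPrevalence:
    """Prevalence implied by assuming one case every ``years_per_case`` years."""

    years_per_case: float
    births_per_year: int

    def __post_init__(self) -> None:
        if self.years_per_case <= 0 or self.births_per_year <= 0:
            raise ValueError("years_per_case and births_per_year must be positive")

    @property
    def prevalence_per_100k(self) -> float:
        return 1e5 / (self.years_per_case * self.births_per_year)

    @property
    def prevalence_per_100k_2dp(self) -> float:
        return round_half_up(self.prevalence_per_100k)


def cumulative_pathogenic_frequency(variants: Sequence[AnnotatedVariant]) -> float:
    """Pooled pathogenic allele frequency q = (sum of AC) / AN.

    The input should already be restricted to filter-passing,
    known-pathogenic variants, all counted over the same cohort allele
    number.  An empty list yields q = 0 with a warning.
    """
    variants = list(variants)
    if not variants:
        warnings.warn("no pathogenic variants: cumulative frequency is 0", stacklevel=2)
        return 0.0
    ans = {v.cohort_an for v in variants}
    if len(ans) != 1:
        raise ValueError(f"mixed cohort allele numbers: {sorted(ans)}")
    (an,) = ans
    if an == 0:
        raise ValueError("cohort_an is 0")
    return sum(v.cohort_ac for v in variants) / an


def hwe_prevalence(
    q: float,
    births_per_year: int,
    *,
    total_ac: Optional[int] = None,
    total_an: Optional[int] = None,
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Project birth prevalence from the pooled allele frequency q.

    When the underlying allele counts are supplied, an exact binomial
    (Clopper-Pearson) interval for q is attached.
    """
    q_ci = None
    if total_ac is not None and total_an is not None:
        q_ci = _clopper_pearson(total_ac, total_an, level)
    return PrevalenceEstimate(q=q, births_per_year=births_per_year,
                              q_ci=q_ci, level=level if q_ci else None)


def scenario_prevalence(years_per_case: float, births_per_year: int) -> ScenarioPrevalence:
    """Prevalence per 100,000 births if one case is born every k years."""
    return ScenarioPrevalence(years_per_case=years_per_case, births_per_year=births_per_year)


def _clopper_pearson(ac: int, an: int, level: float) -> tuple[float, float]:
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0,1), got {level}")
    if not 0 <= ac <= an or an == 0:
        raise ValueError(f"require 0 <= ac <= an with an > 0, got ac={ac}, an={an}")
    alpha = 1.0 - level
    lo = 0.0 if ac == 0 else float(beta.ppf(alpha / 2, ac, an - ac + 1))
    hi = 1.0 if ac == an else float(beta.ppf(1 - alpha / 2, ac + 1, an - ac))
    return lo, hi


def prevalence_interval(
    total_ac: int,
    total_an: int,
    births_per_year: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Exact-binomial interval for the prevalence per 100,000 births.

    Clopper-Pearson interval for q from (total_ac, total_an); the endpoints
    are squared and scaled by 1e5.  Contains the point estimate
    ``(ac/an)^2 * 1e5`` by monotonicity of squaring on [0,1].
    """
    if births_per_year <= 0:
        raise ValueError("births_per_year must be positive")
    lo, hi = _clopper_pearson(total_ac, total_an, level)
    return lo * lo * 1e5, hi * hi * 1e5


def pooled_mean_prevalence(values: Iterable[float]) -> float:
    """Arithmetic mean of per-100k prevalences from independent studies."""
    values = list(values)
    if not values:
        raise ValueError("empty list of prevalences")
    return sum(values) / len(values)
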