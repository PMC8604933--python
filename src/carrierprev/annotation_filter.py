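"""Rare damaging-variant filter cascade.

Selects rare, predicted-damaging, evolutionarily conserved missense and
indel variants from an annotated cohort, the candidate set that is then
curated (here: a ``known_pathogenic`` membership flag) before prevalence
estimation.

A variant passes when ALL of the following hold (strict inequalities):

* consequence is missense or indel,
* reference-population allele frequency < ``af_max`` (default 1%),
* CADD (PHRED-scaled) > ``cadd_min`` (default 15),
* damage: ``1 - SIFT > damage_min`` OR ``PolyPhen2 > damage_min``
  (default 0.75; SIFT is damaging when *low*, so it is inverted to share
  PolyPhen2's orientation),
* conservation: ``GERP > gerp_min`` (default 5) OR phastCons element score
  > ``phastcons_min`` (default 500, on the 0-1000 element-score scale).

A missing score fails its own clause, but a present partner in an OR-group
can still satisfy the group; an unscored variant can never pass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "AnnotatedVariant",
    "FilterCriteria",
    "FilterDecision",
    "passes_filter",
    "filter_cohort",
    "decisions_to_tsv",
]

#: clause labels, in reporting order
CLAUSES = ("consequence", "rarity", "cadd", "damage", "conservation")

CONSEQUENCES = ("missense", "indel", "other")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant site with functional annotations and cohort counts.

    Coordinates are 1-based (VCF convention).  Any score may be ``None``
    (not annotated).  ``reference_af`` is a gnomAD-style population allele
    frequency; ``reference_n_individuals`` the number of sequenced
    individuals behind it.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    hgvs_p: str = ""
    cadd_phred: Optional[float] = None
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    cohort_ac: int = 0
    cohort_an: int = 0
    reference_af: Optional[float] = None
    reference_n_individuals: Optional[int] = None
    known_pathogenic: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.cohort_ac <= self.cohort_an:
            raise ValueError(
                f"require 0 <= cohort_ac <= cohort_an, got "
                f"ac={self.cohort_ac}, an={self.cohort_an}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for name in ("sift", "polyphen2"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {val}")
        if self.reference_af is not None and not 0.0 <= self.reference_af <= 1.0:
            raise ValueError(f"reference_af must lie in [0,1], got {self.reference_af}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def cohort_af(self) -> float:
        if self.cohort_an == 0:
            raise ValueError("cohort_an is 0; allele frequency undefined")
        return self.cohort_ac / self.cohort_an


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the filter cascade; defaults are the screening values."""

    af_max: float = 0.01
    cadd_min: float = 15.0
    damage_min: float = 0.75
    gerp_min: float = 5.0
    phastcons_min: float = 500.0
    allowed_consequences: frozenset = frozenset({"missense", "indel"})

    def __post_init__(self) -> None:
        if not 0.0 < self.af_max <= 1.0:
            raise ValueError(f"af_max must lie in (0,1], got {self.af_max}")
        for name in ("cadd_min", "damage_min", "gerp_min", "phastcons_min"):
            val = getattr(self, name)
            if val != val or val in (float("inf"),):
                raise ValueError(f"{name} must be finite or -inf, got {val}")
        object.__setattr__(
            self, "allowed_consequences", frozenset(self.allowed_consequences)
        )

    def relaxed(self, **overrides) -> "FilterCriteria":
        return replace(self, **overrides)


@dataclass(frozen=True)
class FilterDecision:
    """Audit record for one variant: pass/fail plus the clauses that failed."""

    variant_id: str
    passed: bool
    failed_criteria: tuple

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must be equivalent to empty failed_criteria")


def _gt(value: Optional[float], threshold: float) -> bool:
    """Strict comparison treating a missing score as a failure."""
    return value is not None and value > threshold


def passes_filter(v: AnnotatedVariant, c: FilterCriteria = FilterCriteria()) -> FilterDecision:
    """Evaluate the five filter clauses for one variant.

    Returns a :class:`FilterDecision`; ``passed`` is the conjunction of the
    clauses and every failed clause is named in ``failed_criteria``.
    """
    failed = []
    if v.consequence not in c.allowed_consequences:
        failed.append("consequence")
    if not (v.reference_af is not None and v.reference_af < c.af_max):
        failed.append("rarity")
    if not _gt(v.cadd_phred, c.cadd_min):
        failed.append("cadd")
    inv_sift = None if v.sift is None else 1.0 - v.sift
    if not (_gt(inv_sift, c.damage_min) or _gt(v.polyphen2, c.damage_min)):
        failed.append("damage")
    if not (_gt(v.gerp, c.gerp_min) or _gt(v.phastcons, c.phastcons_min)):
        failed.append("conservation")
    return FilterDecision(v.variant_id, passed=not failed, failed_criteria=tuple(failed))


def filter_cohort(
    variants: Iterable[AnnotatedVariant],
    c: FilterCriteria = FilterCriteria(),
) -> tuple[list[AnnotatedVariant], Counter, list[FilterDecision]]:
    """Apply :func:`passes_filter` to a cohort.

    Returns ``(passing, tally, decisions)`` where ``passing`` preserves
    input order and ``tally`` counts each failed clause over all variants.
    """
    passing: list[AnnotatedVariant] = []
    tally: Counter = Counter()
    decisions: list[FilterDecision] = []
    for v in variants:
        d = passes_filter(v, c)
        decisions.append(d)
        if d.passed:
            passing.append(v)
        tally.update(d.failed_criteria)
    return passing, tally, decisions


def decisions_to_tsv(decisions: Sequence[FilterDecision]) -> str:
    """Render decisions as TSV (variant id, passed, semicolon-joined clauses)."""
    lines = ["variant_id\tpassed\tfailed_criteria"]
    for d in decisions:
        lines.append(f"{d.variant_id}\t{str(d.passed).lower()}\t{';'.join(d.failed_criteria)}")
    return "\n".join(lines) + "\n"
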