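"""Enrichment statistics against brute-force oracles.

The one-sided exact test is checked against exhaustive hypergeometric
enumeration; the conditional-MLE odds ratio against a grid/golden-section
maximiser of the explicitly summed conditional likelihood and against
scipy's independent conditional estimator.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from carrierprev import (
    AnnotatedVariant,
    ContingencyTable2x2,
    allele_frequency,
    enrich_all,
    fisher_one_sided,
    odds_ratio_cmle,
    reconstruct_reference_counts,
    sample_odds_ratio,
)

# ---------------------------------------------------------------------------
# oracles


def enumeration_p(t: ContingencyTable2x2) -> Fraction:
    """Exact upper-tail P(X >= a) by exhaustive enumeration, in rationals."""
    M, K, n = t.total, t.a + t.c, t.a + t.b
    num = sum(math.comb(K, x) * math.comb(M - K, n - x)
              for x in range(t.a, min(n, K) + 1))
    return Fraction(num, math.comb(M, n))


def brute_force_cmle(t: ContingencyTable2x2) -> float:
    """Maximise the explicitly summed conditional likelihood over log-odds."""
    M, K, n = t.total, t.a + t.c, t.a + t.b
    lo, hi = max(0, n + K - M), min(n, K)
    xs = np.arange(lo, hi + 1)
    logw = np.array([
        math.lgamma(K + 1) - math.lgamma(x + 1) - math.lgamma(K - x + 1)
        + math.lgamma(M - K + 1) - math.lgamma(n - x + 1)
        - math.lgamma(M - K - n + x + 1)
        for x in xs
    ])

    def neg_loglik(log_psi):
        terms = logw + xs * log_psi
        m = terms.max()
        return -(logw[t.a - lo] + t.a * log_psi - (m + np.log(np.exp(terms - m).sum())))

    res = minimize_scalar(neg_loglik, bounds=(-30, 30), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# allele frequencies and count reconstruction


@pytest.mark.parametrize(
    "ac, an, expected_3sf",
    [(3, 2032, "1.48e-03"), (2, 2032, "9.84e-04"), (0, 2032, "0.00e+00")],
)
def test_allele_frequency_printed_precision(ac, an, expected_3sf):
    assert f"{allele_frequency(ac, an):.2e}" == expected_3sf


def test_allele_frequency_rejects_bad_counts():
    with pytest.raises(ValueError):
        allele_frequency(1, 0)
    with pytest.raises(ValueError):
        allele_frequency(5, 4)


@pytest.mark.parametrize(
    "af, n, expected",
    [(1.79e-5, 55852, (2, 111704)), (3.94e-4, 55852, (44, 111704)),
     (0.0, 55852, (0, 111704))],
)
def test_reconstruct_reference_counts(af, n, expected):
    ac, an = reconstruct_reference_counts(af, n)
    assert (ac, an) == expected
    # round trip at the reported precision
    if ac:
        assert f"{ac / an:.2e}" == f"{af:.2e}"


# ---------------------------------------------------------------------------
# one-sided exact test


@pytest.mark.parametrize(
    "cells",
    [(3, 2029, 2, 111702), (2, 2030, 44, 111660), (2, 2, 1, 3),
     (0, 10, 3, 7), (5, 0, 0, 5), (1, 1, 1, 1)],
)
def test_p_matches_exhaustive_enumeration(cells):
    t = ContingencyTable2x2(*cells)
    assert fisher_one_sided(t) == pytest.approx(float(enumeration_p(t)), rel=1e-10)


def test_small_table_exact_rational():
    # P(X>=2) = (C(3,2)C(5,2)+C(3,3)C(5,1)) / C(8,4) = 35/70
    assert enumeration_p(ContingencyTable2x2(2, 2, 1, 3)) == Fraction(1, 2)
    assert fisher_one_sided(ContingencyTable2x2(2, 2, 1, 3)) == pytest.approx(0.5)


def test_zero_alt_in_cohort_gives_p_one():
    assert fisher_one_sided(ContingencyTable2x2(0, 2032, 7, 111697)) == 1.0


def test_all_zero_table_rejected():
    with pytest.raises(ValueError):
        fisher_one_sided(ContingencyTable2x2(0, 0, 0, 0))


@given(st.integers(0, 8), st.integers(1, 8), st.integers(0, 8), st.integers(0, 8))
def test_more_cohort_alt_never_increases_p(a, b, c, d):
    t = ContingencyTable2x2(a, b, c, d)
    shifted = ContingencyTable2x2(a + 1, b - 1, c, d)
    assert fisher_one_sided(shifted) <= fisher_one_sided(t) + 1e-12


# ---------------------------------------------------------------------------
# conditional-MLE odds ratio


@pytest.mark.parametrize(
    "cells, expected, sf",
    [((2, 2030, 44, 111660), 2.5, 2), ((1, 9, 1, 9), 1.0, 3)],
)
def test_cmle_reference_values(cells, expected, sf):
    assert float(f"{odds_ratio_cmle(ContingencyTable2x2(*cells)):.{sf}g}") == expected


def small_tables():
    """Deterministic battery: all tables with total <= 9 plus a seeded
    sample of tables with total <= 60 (interior a, non-degenerate margins)."""
    tables = []
    for total in range(2, 10):
        for a in range(total + 1):
            for b in range(total + 1 - a):
                for c in range(total + 1 - a - b):
                    d = total - a - b - c
                    tables.append((a, b, c, d))
    rng = np.random.default_rng(2024)
    for _ in range(250):
        cells = rng.multinomial(int(rng.integers(10, 61)), [0.25] * 4)
        tables.append(tuple(int(x) for x in cells))
    return tables


def test_cmle_equals_brute_force_on_small_tables():
    checked = 0
    for cells in small_tables():
        t = ContingencyTable2x2(*cells)
        if t.a + t.c == 0 or t.a + t.b == 0:
            continue
        lo = max(0, (t.a + t.b) + (t.a + t.c) - t.total)
        hi = min(t.a + t.b, t.a + t.c)
        if t.a in (lo, hi):  # boundary: MLE is 0 or infinity by convention
            continue
        est = odds_ratio_cmle(t)
        assert est == pytest.approx(brute_force_cmle(t), rel=1e-3), cells
        checked += 1
    assert checked > 300


@pytest.mark.parametrize(
    "cells", [(3, 2029, 2, 111702), (2, 2030, 44, 111660), (7, 13, 5, 25)]
)
def test_cmle_agrees_with_independent_library_estimator(cells):
    t = ContingencyTable2x2(*cells)
    ref = scipy_odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional").statistic
    assert odds_ratio_cmle(t) == pytest.approx(ref, rel=1e-6)


@given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 20), st.integers(1, 20))
def test_cmle_symmetries(a, b, c, d):
    """Swapping alt/ref columns inverts the conditional MLE; transposing
    the table (swapping which margin is conditioned on) leaves it unchanged."""
    t = ContingencyTable2x2(a, b, c, d)
    est = odds_ratio_cmle(t)
    if math.isfinite(est) and est > 0:
        assert odds_ratio_cmle(t.allele_swapped()) == pytest.approx(1.0 / est, rel=1e-6)
        assert odds_ratio_cmle(t.transposed()) == pytest.approx(est, rel=1e-6)


def test_cmle_boundaries():
    assert odds_ratio_cmle(ContingencyTable2x2(0, 10, 5, 5)) == 0.0
    assert odds_ratio_cmle(ContingencyTable2x2(5, 5, 0, 10)) == math.inf
    with pytest.raises(ValueError):
        odds_ratio_cmle(ContingencyTable2x2(0, 10, 0, 10))


def test_cmle_approaches_sample_or_for_large_balanced_tables():
    t = ContingencyTable2x2(600, 500, 500, 700)
    assert odds_ratio_cmle(t) == pytest.approx(sample_odds_ratio(t), rel=0.01)


# ---------------------------------------------------------------------------
# sample odds ratio


def test_sample_odds_ratio():
    assert sample_odds_ratio(ContingencyTable2x2(3, 2029, 2, 111702)) == pytest.approx(
        335106 / 4058
    )
    assert sample_odds_ratio(ContingencyTable2x2(1, 9, 1, 9)) == 1.0
    assert sample_odds_ratio(ContingencyTable2x2(1, 9, 0, 10)) is None


# ---------------------------------------------------------------------------
# batch interface


def make_variant(pos, ac, ref_af, ref_n=55_852, an=2032):
    return AnnotatedVariant(
        chrom="18", pos=pos, ref="C", alt="T", consequence="missense",
        cohort_ac=ac, cohort_an=an, reference_af=ref_af,
        reference_n_individuals=ref_n,
    )


def test_enrich_all_sorted_and_complete():
    vs = [make_variant(1, 2, 3.94e-4), make_variant(2, 3, 1.79e-5)]
    res = enrich_all(vs)
    assert [r.variant_id for r in res] == ["18:2:C>T", "18:1:C>T"]  # p ascending
    assert res[0].p_one_sided < res[1].p_one_sided
    assert all(r.error is None for r in res)


def test_enrich_all_matched_frequencies_not_significant():
    # cohort AF equals reference AF: odds ratio near 1, p clearly > 0.05
    v = make_variant(1, ac=20, ref_af=20 / 2032, ref_n=10_000)
    (r,) = enrich_all([v])
    assert r.p_one_sided > 0.05
    assert r.or_cmle == pytest.approx(1.0, abs=0.05)


def test_enrich_all_flags_bad_rows_without_aborting():
    vs = [make_variant(1, 3, 1.79e-5), make_variant(2, 2, None)]
    res = enrich_all(vs)
    assert len(res) == 2
    ok = [r for r in res if r.error is None]
    bad = [r for r in res if r.error is not None]
    assert len(ok) == 1 and len(bad) == 1
    assert bad[0].p_one_sided is None


def test_enrich_all_empty():
    assert enrich_all([]) == []
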