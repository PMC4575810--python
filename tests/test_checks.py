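"""Unit and property tests for the six discrepancy checks."""

import math
from decimal import Decimal, ROUND_HALF_EVEN, ROUND_HALF_UP
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trialaudit import (
    FactualPair,
    InvalidClaimError,
    PercentageClaim,
    ReportClaims,
    SumClaim,
    SummaryStatClaim,
    TwoGroupClaim,
    audit_report,
    check_factual,
    check_missed_p,
    check_percentage,
    check_sum,
    check_summary_stats,
    feasible_counts,
    two_group_p,
    two_group_test,
)
from conftest import table1_claims


# --- feasible_counts -------------------------------------------------------

def _feasible_oracle(reported, den, decimals):
    """Independent enumeration using exact Fraction arithmetic."""
    target = Fraction(str(reported))
    out = set()
    for k in range(den + 1):
        pct = Fraction(100 * k, den)
        scaled = pct * 10 ** decimals
        floor = scaled.numerator // scaled.denominator
        rem = scaled - floor
        if rem < Fraction(1, 2):
            candidates = {floor}
        elif rem > Fraction(1, 2):
            candidates = {floor + 1}
        else:  # exact half: half-up and half-even
            candidates = {floor + 1, floor if floor % 2 == 0 else floor + 1}
        if any(Fraction(c, 10 ** decimals) == target for c in candidates):
            out.add(k)
    return out


@pytest.mark.parametrize("reported, den, decimals, expected", [
    (42, 57, 0, {24}),        # 42% of 57 can only come from 24 patients
    (31.2, 200, 1, set()),    # granularity 0.5% makes 31.2% impossible
    (0, 10, 0, {0}),
    (40, 57, 0, {23}),
    (50, 2, 0, {1}),
    (100, 3, 0, {3}),
])
def test_feasible_counts_examples(reported, den, decimals, expected):
    assert set(feasible_counts(reported, den, decimals)) == expected


@given(
    den=st.integers(1, 500),
    decimals=st.integers(0, 2),
    scaled=st.integers(0, 1050),
)
@settings(max_examples=60)
def test_feasible_counts_matches_bruteforce(den, decimals, scaled):
    reported = scaled / 10 ** decimals if decimals else scaled
    got = set(feasible_counts(reported, den, decimals))
    assert got == _feasible_oracle(reported, den, decimals)


def test_feasible_counts_rejects_bad_inputs():
    with pytest.raises(InvalidClaimError):
        feasible_counts(42, 0, 0)
    with pytest.raises(InvalidClaimError):
        feasible_counts(42.5, 100, 0)  # more precision than declared


# --- check_percentage ------------------------------------------------------

def test_check_percentage_worked_examples():
    res = check_percentage(PercentageClaim(denominator=57, reported_percent=42,
                                           numerator=23))
    assert res.flagged and res.category == "possible_percentage"
    assert res.detail["feasible_counts"] == [24]

    ok = check_percentage(PercentageClaim(denominator=57, reported_percent=40,
                                          numerator=23))
    assert not ok.flagged

    imp = check_percentage(PercentageClaim(denominator=200, reported_percent=31.2,
                                           percent_decimals=1))
    assert imp.flagged and imp.category == "impossible_percentage"
    assert imp.detail["feasible_counts"] == []


@given(n=st.integers(1, 500), data=st.data())
@settings(max_examples=60)
def test_consistent_percentage_never_flagged(n, data):
    k = data.draw(st.integers(0, n))
    reported = round(100 * k / n)
    res = check_percentage(PercentageClaim(denominator=n, reported_percent=reported,
                                           numerator=k))
    assert not res.flagged


def test_percentage_above_100_is_checkable():
    res = check_percentage(PercentageClaim(denominator=50, reported_percent=150))
    assert res.flagged and res.category == "impossible_percentage"


# --- check_summary_stats ---------------------------------------------------

def _max_sample_sd_grid(lo, hi, n, steps=21):
    """Exhaustive grid oracle: max sample SD over n-point datasets in [lo, hi]."""
    from itertools import combinations_with_replacement
    grid = np.linspace(lo, hi, steps)
    best = 0.0
    for xs in combinations_with_replacement(grid, n):
        best = max(best, float(np.std(xs, ddof=1)))
    return best


@pytest.mark.parametrize("claim, flagged, rule", [
    (SummaryStatClaim(median=13, min=14, max=444), True, "median_outside_range"),
    (SummaryStatClaim(mean=5, min=0, max=10, sd=0, n=2), False, None),
    (SummaryStatClaim(mean=5, min=4, max=6, sd=3, n=4), True, "sd_exceeds_bound"),
    (SummaryStatClaim(mean=12, min=0, max=10), True, "mean_outside_range"),
    (SummaryStatClaim(sd=-1.0), True, "negative_sd"),
])
def test_summary_stat_rules(claim, flagged, rule):
    res = check_summary_stats(claim)
    assert res.flagged == flagged
    if rule:
        assert rule in res.detail["violations"]


def test_sd_bound_matches_grid_maximum():
    # no 4-point dataset in [4, 6] reaches SD 3; the extremal split reaches
    # the closed-form bound (6-4)/2 * sqrt(4/3)
    bound = (6 - 4) / 2 * math.sqrt(4 / 3)
    assert _max_sample_sd_grid(4, 6, 4) == pytest.approx(bound, abs=1e-9)
    assert 3 > bound


def test_summary_untestable_is_explicit():
    res = check_summary_stats(SummaryStatClaim(mean=5.0))
    assert not res.flagged
    assert res.detail == {"untestable": True}


@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=40))
def test_summary_stats_of_real_samples_never_flagged(xs):
    x = np.asarray(xs)
    claim = SummaryStatClaim(
        n=len(xs), mean=float(x.mean()), median=float(np.median(x)),
        sd=float(x.std(ddof=1)), min=float(x.min()), max=float(x.max()))
    assert not check_summary_stats(claim).flagged


# --- check_sum -------------------------------------------------------------

@pytest.mark.parametrize("parts, total, flagged, computed", [
    ([5, 5, 6], 15, True, 16),
    ([5, 5, 6], 16, False, 16),
    ([0], 0, False, 0),
    ([-3], -3, False, -3),  # before/after/change encoding
])
def test_check_sum(parts, total, flagged, computed):
    res = check_sum(SumClaim(parts=parts, stated_total=total))
    assert res.flagged == flagged
    assert res.detail["computed_sum"] == computed


# --- two_group_p / check_missed_p -----------------------------------------

def test_two_group_welch_against_direct_formulas():
    m1, s1, n1, m2, s2, n2 = 29.4, 12.7, 191, 36.1, 13.8, 200
    t, df, p = two_group_test(m1, s1, n1, m2, s2, n2)
    se2 = s1**2 / n1 + s2**2 / n2
    t_direct = (m1 - m2) / math.sqrt(se2)
    df_direct = se2**2 / ((s1**2 / n1)**2 / (n1 - 1) + (s2**2 / n2)**2 / (n2 - 1))
    assert t == pytest.approx(t_direct)
    assert abs(t) == pytest.approx(4.999, abs=5e-3)
    assert df == pytest.approx(df_direct)
    assert df == pytest.approx(388.2, abs=0.5)
    assert p < 0.001


def test_two_group_p_matches_scipy():
    for variant, equal_var in (("welch", False), ("pooled", True)):
        res = stats.ttest_ind_from_stats(29.4, 12.7, 191, 36.1, 13.8, 200,
                                         equal_var=equal_var)
        assert two_group_p(29.4, 12.7, 191, 36.1, 13.8, 200, variant) == \
            pytest.approx(res.pvalue, rel=1e-9)


def test_two_group_degenerate_inputs():
    assert two_group_p(10, 0, 5, 10, 0, 5) == 1.0
    with pytest.warns(RuntimeWarning):
        assert two_group_p(10, 0, 5, 11, 0, 5) == 0.0


@given(
    m1=st.floats(-50, 50), m2=st.floats(-50, 50),
    s1=st.floats(0.5, 20), s2=st.floats(0.5, 20),
    n1=st.integers(2, 500), n2=st.integers(2, 500),
    shift=st.floats(-100, 100),
)
def test_two_group_p_swap_and_shift_invariance(m1, m2, s1, s2, n1, n2, shift):
    p = two_group_p(m1, s1, n1, m2, s2, n2)
    assert two_group_p(m2, s2, n2, m1, s1, n1) == pytest.approx(p, rel=1e-12)
    assert two_group_p(m1 + shift, s1, n1, m2 + shift, s2, n2) == \
        pytest.approx(p, rel=1e-6)


def test_check_missed_p():
    claim = TwoGroupClaim(mean1=29.4, sd1=12.7, n1=191, mean2=36.1, sd2=13.8,
                          n2=200, asserted_comparable=True)
    res = check_missed_p(claim)
    assert res.flagged and res.detail["p"] < 0.001

    not_asserted = TwoGroupClaim(mean1=29.4, sd1=12.7, n1=191, mean2=36.1,
                                 sd2=13.8, n2=200, asserted_comparable=False)
    assert not check_missed_p(not_asserted).flagged

    similar = TwoGroupClaim(mean1=10, sd1=2, n1=50, mean2=10.1, sd2=2, n2=50,
                            asserted_comparable=True)
    res = check_missed_p(similar)
    assert not res.flagged
    assert res.detail["p"] == pytest.approx(0.80, abs=0.01)


# --- check_factual ---------------------------------------------------------

@pytest.mark.parametrize("a, b, decimals, flagged", [
    (1.04, 1.16, 2, True),
    (1.04, 1.04, 2, False),
    (1.0, 1.04, 1, False),   # 1.04 prints as 1.0 at one decimal
    (1.0, 1.06, 1, True),
    (191, 200, 0, True),
])
def test_check_factual(a, b, decimals, flagged):
    res = check_factual(FactualPair(value_a=a, value_b=b, decimals=decimals))
    assert res.flagged == flagged


def test_factual_rounding_convention_is_conservative():
    # 2.5 vs 2.4999: at 0 decimals half-even gives 2 vs 2; "either" must not flag
    pair = FactualPair(value_a=2.5, value_b=2.4999, decimals=0)
    assert not check_factual(pair, rounding="either").flagged
    assert check_factual(pair, rounding="half_up").flagged


# --- audit_report ----------------------------------------------------------

def test_audit_worked_examples_one_flag_per_category(table1_report):
    profile = audit_report(table1_report)
    assert profile.total == 6
    assert all(v == 1 for v in profile.counts.values())


def test_audit_empty_report():
    profile = audit_report(ReportClaims(report_id="empty", claims=[]))
    assert profile.total == 0
    assert all(v == 0 for v in profile.counts.values())


def test_audit_total_additive_over_concatenation():
    claims = table1_claims()
    single = audit_report(ReportClaims(report_id="x", claims=claims))
    triple = audit_report(ReportClaims(report_id="x", claims=claims * 3))
    assert triple.total == 3 * single.total
    assert all(triple.counts[c] == 3 * single.counts[c] for c in triple.counts)


def test_audit_names_offending_claim():
    bad = ReportClaims.__new__(ReportClaims)
    bad.report_id = "bad"
    bad.claims = [table1_claims()[0], "not a claim"]
    with pytest.raises(InvalidClaimError, match="claim 1"):
        audit_report(bad)


# --- claim validation ------------------------------------------------------

@pytest.mark.parametrize("make", [
    lambda: PercentageClaim(denominator=0, reported_percent=10),
    lambda: PercentageClaim(denominator=10, reported_percent=50, numerator=11),
    lambda: SummaryStatClaim(min=5, max=4),
    lambda: TwoGroupClaim(mean1=1, sd1=0, n1=5, mean2=2, sd2=0, n2=5),
    lambda: TwoGroupClaim(mean1=1, sd1=1, n1=1, mean2=2, sd2=1, n2=5),
    lambda: SumClaim(parts=[], stated_total=0),
    lambda: FactualPair(value_a=1, value_b=2, decimals=-1),
])
def test_invalid_claims_rejected(make):
    with pytest.raises(InvalidClaimError):
        make()
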