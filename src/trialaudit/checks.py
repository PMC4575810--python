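"""The six discrepancy checks, applied claim-by-claim and tallied per report.

Categories:

* ``possible_percentage`` — the printed percentage does not match the
  printed numerator/denominator but some other integer count would yield
  it ("42% of 57" cannot come from 23 patients, but could from 24).
* ``impossible_percentage`` — no integer count yields the printed
  percentage for the stated group size (a granularity violation: 31.2%
  of 200 would require fractional patients).
* ``factual`` — the same quantity printed with two different values.
* ``impossible_summary`` — summary statistics that no dataset can
  produce (median outside the range, SD above its algebraic maximum).
* ``arithmetical`` — subgroups that do not add to the stated total.
* ``missed_p`` — two groups described as comparable whose printed
  mean/SD/n imply a significant difference.

Rounding convention: a printed value is taken as consistent with an
exact value if it matches under *either* round-half-up or round-half-even
at the printed precision (the conservative choice: fewer false flags,
since the source's rounding rule is unknowable). Pass ``rounding=
"half_up"`` or ``"half_even"`` to pin one convention.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import FrozenSet, Iterable, Optional

import numpy as np
from scipy import stats

from .claims import (
    CATEGORIES,
    CheckResult,
    FactualPair,
    InvalidClaimError,
    NumericClaim,
    PercentageClaim,
    ReportClaims,
    ReportProfile,
    SumClaim,
    SummaryStatClaim,
    TwoGroupClaim,
)

__all__ = [
    "feasible_counts",
    "check_percentage",
    "check_summary_stats",
    "check_sum",
    "two_group_test",
    "two_group_p",
    "check_missed_p",
    "check_factual",
    "check_claim",
    "check_claims",
    "audit_report",
]

ROUNDING_MODES = ("either", "half_up", "half_even")


def _round_scaled(num: int, den: int, mode: str) -> int:
    """Round the non-negative rational num/den to the nearest integer."""
    q, r = divmod(num, den)
    twice = 2 * r
    if twice < den:
        return q
    if twice > den:
        return q + 1
    if mode == "half_up":
        return q + 1
    return q if q % 2 == 0 else q + 1  # half to even


def _scaled_percent(reported_percent: float, decimals: int) -> int:
    """The reported percentage as an integer in units of 10^-decimals %."""
    scaled = reported_percent * 10 ** decimals
    target = round(scaled)
    if abs(scaled - target) > 1e-6:
        raise InvalidClaimError(
            f"reported percent {reported_percent} is not representable "
            f"at {decimals} decimal places")
    return target


def feasible_counts(
    reported_percent: float,
    denominator: int,
    percent_decimals: int = 0,
    rounding: str = "either",
) -> FrozenSet[int]:
    """All integer counts k in [0, denominator] that print as the reported %.

    A count k is feasible when 100*k/denominator, rounded to
    ``percent_decimals`` places under the rounding convention, equals
    ``reported_percent``. An empty set means the percentage is
    impossible for this group size.
    """
    if not isinstance(denominator, int) or denominator < 1:
        raise InvalidClaimError("denominator must be an integer >= 1")
    if percent_decimals < 0:
        raise InvalidClaimError("percent_decimals must be >= 0")
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding must be one of {ROUNDING_MODES}")
    target = _scaled_percent(reported_percent, percent_decimals)
    modes = ("half_up", "half_even") if rounding == "either" else (rounding,)
    scale = 10 ** percent_decimals
    out = set()
    for k in range(denominator + 1):
        num = 100 * k * scale
        if any(_round_scaled(num, denominator, m) == target for m in modes):
            out.add(k)
    return frozenset(out)


def check_percentage(claim: PercentageClaim, rounding: str = "either") -> CheckResult:
    """Check a printed percentage against its group size (and numerator)."""
    feas = feasible_counts(claim.reported_percent, claim.denominator,
                           claim.percent_decimals, rounding)
    detail = {
        "feasible_counts": sorted(feas),
        "reported_percent": claim.reported_percent,
        "denominator": claim.denominator,
    }
    if not feas:
        return CheckResult("impossible_percentage", True, detail)
    if claim.numerator is not None and claim.numerator not in feas:
        detail["numerator"] = claim.numerator
        return CheckResult("possible_percentage", True, detail)
    return CheckResult("possible_percentage", False, detail)


# SD of n points confined to [lo, hi] is maximized by an even split onto the
# endpoints; for the sample (n-1 denominator) SD the bound is
# (hi-lo)/2 * sqrt(n/(n-1)) -- attained at even n, an upper bound at odd n.
def _sd_bound(min_: float, max_: float, n: int) -> float:
    return (max_ - min_) / 2.0 * np.sqrt(n / (n - 1.0))


def check_summary_stats(claim: SummaryStatClaim) -> CheckResult:
    """Flag summary statistics that no dataset can produce.

    Rules, each applied only when its operands are present:

    a. median must lie within [min, max]
    b. mean must lie within [min, max]
    c. sd must be non-negative
    d. sd must not exceed (max-min)/2 * sqrt(n/(n-1))

    A claim supporting none of the rules yields an explicit
    "untestable" result (not flagged) so that audits are reproducible
    from their logs.
    """
    violations = []
    testable = False
    if claim.median is not None and claim.min is not None and claim.max is not None:
        testable = True
        if not (claim.min <= claim.median <= claim.max):
            violations.append("median_outside_range")
    if claim.mean is not None and claim.min is not None and claim.max is not None:
        testable = True
        if not (claim.min <= claim.mean <= claim.max):
            violations.append("mean_outside_range")
    if claim.sd is not None:
        testable = True
        if claim.sd < 0:
            violations.append("negative_sd")
        if claim.n is not None and claim.n >= 2 and claim.min is not None \
                and claim.max is not None:
            bound = _sd_bound(claim.min, claim.max, claim.n)
            if claim.sd > bound + 1e-12:
                violations.append("sd_exceeds_bound")
    if not testable:
        return CheckResult("impossible_summary", False, {"untestable": True})
    if violations:
        detail = {"violations": violations}
        if "sd_exceeds_bound" in violations:
            detail["sd_bound"] = _sd_bound(claim.min, claim.max, claim.n)
        return CheckResult("impossible_summary", True, detail)
    return CheckResult("impossible_summary", False, {"violations": []})


def check_sum(claim: SumClaim) -> CheckResult:
    """Flag subgroup counts that do not add to the stated total."""
    computed = sum(claim.parts)
    flagged = computed != claim.stated_total
    return CheckResult(
        "arithmetical", flagged,
        {"computed_sum": computed, "stated_total": claim.stated_total},
    )


def two_group_test(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "welch",
):
    """Two-sample t test from summary statistics.

    Returns ``(t, df, p)``. ``variant`` is ``"welch"`` (unequal
    variances, Satterthwaite df; the default) or ``"pooled"``.
    Degenerate inputs (both SDs zero) yield p = 1 for equal means and
    p = 0, with a warning, for unequal means.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        warnings.warn("both SDs are zero with unequal means; p set to 0",
                      RuntimeWarning, stacklevel=2)
        return np.inf, float(n1 + n2 - 2), 0.0
    v1, v2 = sd1 ** 2, sd2 ** 2
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = float(n1 + n2 - 2)
    t = (mean1 - mean2) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def two_group_p(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> float:
    """Two-sided p-value for the difference of two summarized groups."""
    return two_group_test(mean1, sd1, n1, mean2, sd2, n2, variant)[2]


def check_missed_p(
    claim: TwoGroupClaim, alpha: float = 0.05, variant: str = "welch"
) -> CheckResult:
    """Flag a comparability assertion contradicted by the printed statistics."""
    t, df, p = two_group_test(claim.mean1, claim.sd1, claim.n1,
                              claim.mean2, claim.sd2, claim.n2, variant)
    flagged = bool(claim.asserted_comparable and p < alpha)
    return CheckResult(
        "missed_p", flagged,
        {"t": t, "df": df, "p": p, "alpha": alpha, "variant": variant,
         "asserted_comparable": claim.asserted_comparable},
    )


def _quantize(value: float, decimals: int, mode: str) -> Decimal:
    exp = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_HALF_EVEN
    return Decimal(repr(value)).quantize(exp, rounding=rounding)


def check_factual(pair: FactualPair, rounding: str = "either") -> CheckResult:
    """Flag two statements of the same quantity that cannot both be true.

    The two values are compared exactly at the shared printed precision;
    under the "either" convention they agree if they match under either
    rounding rule.
    """
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding must be one of {ROUNDING_MODES}")
    modes = ("half_up", "half_even") if rounding == "either" else (rounding,)
    agree = any(
        _quantize(pair.value_a, pair.decimals, m) == _quantize(pair.value_b, pair.decimals, m)
        for m in modes
    )
    return CheckResult(
        "factual", not agree,
        {"value_a": pair.value_a, "value_b": pair.value_b,
         "decimals": pair.decimals,
         "location_a": pair.location_a, "location_b": pair.location_b},
    )


def check_claim(
    claim: NumericClaim,
    alpha: float = 0.05,
    rounding: str = "either",
    ttest: str = "welch",
) -> CheckResult:
    """Dispatch a claim to its category-appropriate check."""
    if isinstance(claim, PercentageClaim):
        return check_percentage(claim, rounding)
    if isinstance(claim, SummaryStatClaim):
        return check_summary_stats(claim)
    if isinstance(claim, SumClaim):
        return check_sum(claim)
    if isinstance(claim, TwoGroupClaim):
        return check_missed_p(claim, alpha, ttest)
    if isinstance(claim, FactualPair):
        return check_factual(claim, rounding)
    raise InvalidClaimError(f"unknown claim type {type(claim).__name__}")


def check_claims(
    report: ReportClaims,
    alpha: float = 0.05,
    rounding: str = "either",
    ttest: str = "welch",
) -> list:
    """Run every claim of a report through its check, preserving order."""
    results = []
    for i, claim in enumerate(report.claims):
        try:
            results.append(check_claim(claim, alpha, rounding, ttest))
        except InvalidClaimError as exc:
            raise InvalidClaimError(
                f"report {report.report_id!r}, claim {i}: {exc}") from exc
    return results


def audit_report(
    report: ReportClaims,
    alpha: float = 0.05,
    rounding: str = "either",
    ttest: str = "welch",
) -> ReportProfile:
    """Tally flagged checks per category for one report."""
    counts = {c: 0 for c in CATEGORIES}
    for res in check_claims(report, alpha, rounding, ttest):
        if res.flagged:
            counts[res.category] += 1
    return ReportProfile(
        report_id=report.report_id,
        counts=counts,
        total=sum(counts.values()),
        retracted=report.retracted,
        year=report.year,
        impact_factor=report.impact_factor,
        citations=report.citations,
        pair_id=report.pair_id,
    )
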