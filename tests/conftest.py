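import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trialaudit import (
    CATEGORIES,
    FactualPair,
    PercentageClaim,
    ReportClaims,
    ReportProfile,
    SumClaim,
    SummaryStatClaim,
    TwoGroupClaim,
)

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


def table1_claims():
    """The six worked examples of the discrepancy taxonomy, all flaggable."""
    return [
        # 23 of 57 reported as 42%: inconsistent, but 24/57 would fit
        PercentageClaim(denominator=57, reported_percent=42, percent_decimals=0,
                        numerator=23),
        # 31.2% of 200: each patient is 0.5%, so 31.2% is impossible
        PercentageClaim(denominator=200, reported_percent=31.2, percent_decimals=1),
        # base excess 1.04 in the abstract vs 1.16 in the results
        FactualPair(value_a=1.04, value_b=1.16, decimals=2,
                    location_a="abstract", location_b="results"),
        # median stay 13 days with range 14 to 444 days
        SummaryStatClaim(median=13, min=14, max=444),
        # subgroups of 5, 5 and 6 against a stated total of 15
        SumClaim(parts=[5, 5, 6], stated_total=15),
        # ejection fractions 29.4 (12.7, n=191) vs 36.1 (13.8, n=200), "comparable"
        TwoGroupClaim(mean1=29.4, sd1=12.7, n1=191, mean2=36.1, sd2=13.8, n2=200,
                      asserted_comparable=True),
    ]


@pytest.fixture
def table1_report():
    return ReportClaims(report_id="worked-examples", claims=table1_claims(),
                        retracted=True)


def make_profile(report_id, total, retracted, pair_id=None, category="factual",
                 **covariates):
    """A profile with the whole total in one category (test convenience)."""
    counts = {c: 0 for c in CATEGORIES}
    counts[category] = total
    return ReportProfile(report_id=report_id, counts=counts, total=total,
                         retracted=retracted, pair_id=pair_id, **covariates)


def profiles_from_totals(retracted_totals, unretracted_totals):
    """Paired profiles carrying the given per-arm totals."""
    assert len(retracted_totals) == len(unretracted_totals)
    profiles = []
    for i, (r, u) in enumerate(zip(retracted_totals, unretracted_totals)):
        pid = f"pair{i:03d}"
        profiles.append(make_profile(f"{pid}R", r, True, pair_id=pid))
        profiles.append(make_profile(f"{pid}U", u, False, pair_id=pid))
    return profiles
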