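# trialaudit

Screening clinical trial reports for internal numerical discrepancies, and
case-control analysis of discrepancy counts against retraction status.

A *discrepancy* is a pair of mathematically or logically contradictory
statements within one report: a percentage that cannot arise from the stated
group size, a median outside its own range, subgroups that do not add to
their total, two group summaries described as comparable although the
printed means/SDs/n imply P < 0.05. Retracted trial reports carry far more
such discrepancies than unretracted reports from the same journals, which
makes discrepancy counts an accessible early signal of unreliability. This
package is for meta-researchers, journal staff and methodologists who want
to run that screening reproducibly: it takes *structured* numeric claims
(the transcription from free text is up to the reader), applies six
deterministic checks, and provides the statistics of a blinded paired
case-control design on the resulting counts.

## What it computes

**Checks** (module `trialaudit.checks`) — each claim is tested for exactly
one of six categories:

| category | rule |
|---|---|
| possible percentage | reported % does not match k/n at the printed precision, but some other integer count fits |
| impossible percentage | no integer count in [0, n] prints as the reported % |
| factual | the same quantity printed with two unequal values |
| impossible summary | median/mean outside [min, max]; SD < 0; SD > (max−min)/2·√(n/(n−1)) |
| arithmetical | Σ parts ≠ stated total |
| missed P | groups asserted comparable although a two-sample t test (Welch by default) from the printed mean, SD, n gives p < α |

A printed value counts as consistent if it matches under either
round-half-up or round-half-even, so the unknown rounding rule of the
source can never create a false flag.

**Case-control statistics** (module `trialaudit.casecontrol`) — on
per-report count profiles with retraction labels and journal pairing:
paired Wilcoxon signed-rank tests (exact null distribution with midranked
ties up to 25 informative pairs), 2×2 odds ratios with Woolf intervals and
the Haldane–Anscombe +0.5 zero-cell correction, zero-inflated negative
binomial (NB2) regression with incidence rate ratios for the count
component and odds ratios for the excess-zero component, and a
sensitivity/specificity sweep over all count thresholds.

**Synthetic corpora** (module `trialaudit.synthetic`) — paired
retracted/unretracted reports whose counts are drawn from the ZINB model
and then *instantiated* as concrete claims that the checks provably flag
(plus clean distractors they provably pass), so the whole pipeline is
testable end to end against known truth.

## Worked example

```python
from trialaudit import (PercentageClaim, TwoGroupClaim, ReportClaims,
                        audit_report, odds_ratio_ci, TwoByTwo)

report = ReportClaims(report_id="example", claims=[
    # "23 of 57 (42%) of patients ..."
    PercentageClaim(denominator=57, reported_percent=42, numerator=23),
    # "31.2% of 200 patients ..."
    PercentageClaim(denominator=200, reported_percent=31.2, percent_decimals=1),
    # ejection fraction 29.4 (SD 12.7, n=191) vs 36.1 (SD 13.8, n=200),
    # "described as comparable"
    TwoGroupClaim(mean1=29.4, sd1=12.7, n1=191, mean2=36.1, sd2=13.8, n2=200,
                  asserted_comparable=True),
])
profile = audit_report(report)
print(profile.total, profile.counts["possible_percentage"])
# 3 1

res = odds_ratio_ci(TwoByTwo(a=42, b=8, c=24, d=26))  # discrepancy presence
print(f"OR {res.odds_ratio:.1f} ({res.ci_low:.1f} to {res.ci_high:.1f})")
# OR 5.7 (2.2 to 14.5)
```

The first percentage is flagged `possible_percentage` (23/57 is 40%; 42%
of 57 could only arise from 24 patients), the second
`impossible_percentage` (each of 200 patients is 0.5% of the group), the
comparison `missed_p` (Welch p ≈ 9×10⁻⁷). The odds ratio says reports
containing at least one discrepancy had 5.7 times the odds of being
retracted.

From a shell, the same pipeline is:

```sh
trialaudit simulate --pairs 50 --seed 7 --out claims.json --truth truth.json
trialaudit check --claims claims.json --out profiles.csv
trialaudit analyze --profiles profiles.csv --covariates retraction --out analysis/
trialaudit recover --replicates 50 --out recovery.csv
```

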