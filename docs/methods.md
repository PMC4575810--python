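# Methods

## The screening model

Each claim is one *checkable statement*: a unit small enough that a single
deterministic rule decides whether it is internally consistent. The package
deliberately does not read free text; the taxonomy assumes a human (or other
tooling) has transcribed the numbers. Each check answers the question "could
any real dataset have produced this sentence?" and flags the claim only if
the answer is no (or, for percentages, only a *different* dataset could).

### Percentage granularity

For a group of n patients, the printable percentages at d decimal places
form the lattice {round(100k/n, d) : k = 0..n}. `feasible_counts` enumerates
this lattice exactly in integer arithmetic (no floating point): k is
feasible for a reported value r when 100·k·10^d / n rounds to r·10^d. An
inconsistent numerator with a non-empty feasible set is a *possible*
percentage; an empty feasible set is an *impossible* one. Reported values
are validated to be representable at the declared precision; percentages
above 100 are legal inputs (they occur in reports) and are simply checked
against the same lattice.

### Rounding convention

The rounding rule used by a report's authors is unknowable, so the default
convention ("either") accepts a match under round-half-up *or*
round-half-even at the printed precision. This can only reduce flags, never
add them; both single-rule conventions are available for stricter audits.
Printed precision is an explicit field on the claim (`percent_decimals`,
`decimals`) because trailing zeros do not survive numeric transcription.

### Summary-statistic feasibility

Four closed-form rules: median and mean must lie in [min, max]; SD must be
non-negative; and with n, min, max known, the sample SD cannot exceed
(max−min)/2 · √(n/(n−1)) — the extremal dataset splits the points evenly
onto the two endpoints (exact at even n, an upper bound at odd n, verified
against an exhaustive grid search in the tests). Integer-data mean/SD
reconstruction (GRIMMER/SPRITE-style) is deliberately out of scope. A claim
whose present fields support no rule returns an explicit "untestable"
result rather than silently passing, so an audit log is a complete record.

### Missed P values

The two-group check recomputes a two-sided two-sample t test from the
printed mean, SD and n. Welch (unequal variances, Satterthwaite df) is the
default; the pooled-variance test is a configuration option — the choice is
genuinely open and both flag the canonical example (ejection fractions
29.4 (12.7, n=191) vs 36.1 (13.8, n=200): t ≈ −5.0, df ≈ 388, p ≈ 9×10⁻⁷).
α defaults to 0.05 and is configurable. If both SDs are zero the test
degenerates: p = 1 for equal means, p = 0 with a warning otherwise.

### Factual pairs

Two statements of the same quantity are compared exactly at their shared
printed precision under the same either-rounding convention; any mismatch
is a discrepancy, with no tolerance band. Only numeric contradictions are
representable; purely verbal contradictions are outside the data model.

## Case-control statistics

**Pairing.** The design pairs each retracted report with the adjacent
unretracted report in the same journal. Profiles carry an explicit
`pair_id`; paired tests refuse unmatched or mislabeled pairs.

**Wilcoxon signed-rank.** Zero differences are dropped by default (the
common convention; a Pratt-style option keeps them in the ranking — which
rule the original analysis used is not stated). Tied absolute differences
receive midranks. For ≤ 25 informative pairs the exact null distribution of
the rank sum is computed by dynamic programming over doubled midranks
(doubling makes half-integer midranks integral), which remains exact in the
presence of ties; beyond that, a normal approximation with variance
Σrᵢ²/4 (equivalent to the textbook tie-corrected formula). The two-sided p
is 2·min(P(W ≤ w), P(W ≥ w)), capped at 1.

**Odds ratios.** OR = ad/bc with the Woolf interval
exp(log OR ± z·√(1/a+1/b+1/c+1/d)). When any cell is zero, 0.5 is added to
all four cells (Haldane–Anscombe) — required for the threshold sweep, whose
extreme cut-offs always empty a cell. A table with an empty margin raises
rather than returning an arbitrary value.

**Zero-inflated negative binomial.** Counts are modeled as NB2 (variance
μ + μ²/θ; the parameterization of the era's standard R tooling) with a
logit-linear excess-zero component on the same covariates, fitted by
maximum likelihood via `statsmodels.ZeroInflatedNegativeBinomialP`. The fit
is attempted from the default start, then from a data-informed naive start,
with BFGS and Nelder–Mead; a non-converged fit raises with diagnostics
instead of being returned. Standard errors above 25 on the logit scale in
the zero component trigger a separation warning and mark the fit. Year is
centered before fitting so the intercept refers to a mid-window report;
coefficients stay per-year. Count-component coefficients are reported as
incidence rate ratios, zero-component ones as odds ratios, with Wald
intervals.

**Threshold sweep.** For every k from 0 to max(total)+1, sensitivity is the
fraction of retracted reports with ≥ k discrepancies and specificity the
fraction of unretracted reports with < k; both are monotone in k by
construction, with endpoints (1, 0) and (0, 1).

**Quartiles** interpolate linearly between order statistics (numpy's
default). The convention behind published quartiles like 8.75 is
interpolating but not fully identifiable; results with other interpolating
conventions differ by at most one inter-order-statistic gap.

**Multiplicity.** The six per-category tests report raw p values (matching
the original presentation); a Holm adjustment column is available by flag.

## The synthetic-data generator

The generator emulates the study's corpus: `n_pairs` journal pairs (default
50), each one retracted and one unretracted report sharing year and journal
impact factor (adjacent publication in the same journal), with citation
counts per report. Totals are drawn from the ZINB process; each total is
split across the six categories by a multinomial with uniform default
mixture (the published per-category totals exist only as a figure, so no
numbers are hard-coded from it); each category count is then instantiated
as claims constructed to be flagged, verified against the checks at
construction time with bounded retries, among `n_distractors` (default 20)
verified-clean claims — so specificity, not only sensitivity, is exercised,
and the audit round trip is exact by construction on every seed.

Default truth parameters are the fitted magnitudes of the study being
modeled: count intercept ln 4.65 and zero intercept ln 0.78 (the
univariable intercepts), count retraction effect ln 1.79 and zero
retraction effect ln 0.14 (the multivariable retraction effects). The
dispersion θ is not published; θ = 1.0 was fixed once because it reproduces
the corpus-level behaviour (arm means ≈ 2.6 and 7.5 per report, discrepancy
prevalence ≈ 46% and 80% by arm). Covariate distributions — year uniform on
1993–2012, impact factor log-normal (median 3), citations negative binomial
(mean 20) — are arbitrary but documented, with zero effects by default,
matching the null findings for those covariates. These defaults are
illustrative of the study's regime, not a reproduction of its per-report
data.

What the generator does *not* emulate: within-report correlation between
categories beyond multinomial splitting, reader/reviewer behaviour and
inter-rater agreement, non-numeric factual contradictions, and any
dependence of claim difficulty on report characteristics. Passing tests
therefore demonstrate the correctness of the pipeline's mechanics and the
estimator's calibration under the assumed ZINB process, not performance on
real transcribed reports.

## Problem sizes and numerical choices

Parameter-recovery checks use 2,000 simulated reports (1,000 pairs) over a
small fixed seed set for bias, and 100 replicates of 200 reports for null
CI coverage; corpus-level summaries use study-sized corpora (50 pairs)
across tens of seeds. ZINB convergence uses gradient tolerance 1e-8 with
up to 2,000 iterations per start. The SD-bound rule uses a 1e-12 absolute
guard against float noise. All randomness flows from a single
`numpy.random.default_rng` seed; simulated datasets are pure functions of
their parameters including the seed.

## Known limitations

* Published coefficient values of the original regression are not
  reproducible here because the per-report counts live in supplementary
  material; the model's structure and its recovery of known truth on
  synthetic data are the contract instead. The same holds for the published
  70%/66% sensitivity/specificity at a cut-off of three.
* The checks operate on transcribed claims; transcription errors become
  screening errors.
* The exact Wilcoxon distribution conditions on the observed tie pattern,
  as is standard; very heavy ties with few pairs make the two-sided p
  conservative.
* Separation in the excess-zero component (e.g. an arm with no zeros) is
  flagged, not resolved; penalized likelihood is out of scope.
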