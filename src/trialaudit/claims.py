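"""Domain types for numeric claims extracted from clinical trial reports.

A *claim* is one checkable statement transcribed from a report: a
percentage with its group size, a set of summary statistics, a subgroup
sum, a two-group comparison asserted to be non-significant, or a pair of
statements of the same quantity from two places in the text. Claims are
plain frozen dataclasses validated on construction; each carries a
``kind`` tag used by the serialization layer and by the check
dispatcher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence, Union

__all__ = [
    "InvalidClaimError",
    "PercentageClaim",
    "SummaryStatClaim",
    "SumClaim",
    "TwoGroupClaim",
    "FactualPair",
    "NumericClaim",
    "CheckResult",
    "ReportClaims",
    "ReportProfile",
    "CATEGORIES",
]

#: The six discrepancy categories, in canonical order.
CATEGORIES = (
    "possible_percentage",
    "impossible_percentage",
    "factual",
    "impossible_summary",
    "arithmetical",
    "missed_p",
)


class InvalidClaimError(ValueError):
    """A claim violates its structural invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidClaimError(msg)


def _is_num(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool) and math.isfinite(x)


@dataclass(frozen=True)
class PercentageClaim:
    """A reported percentage of a patient group.

    ``numerator`` may be absent when the text states only "X% of N
    patients". ``percent_decimals`` is the number of decimal places the
    percentage was printed with; it cannot be recovered from the numeric
    value (trailing zeros are lost), so it is an explicit field.
    """

    denominator: int
    reported_percent: float
    percent_decimals: int = 0
    numerator: Optional[int] = None

    kind = "percentage"

    def __post_init__(self) -> None:
        _require(isinstance(self.denominator, int) and self.denominator >= 1,
                 "denominator must be an integer >= 1")
        _require(_is_num(self.reported_percent), "reported_percent must be finite")
        _require(isinstance(self.percent_decimals, int) and self.percent_decimals >= 0,
                 "percent_decimals must be an integer >= 0")
        scaled = self.reported_percent * 10 ** self.percent_decimals
        _require(abs(scaled - round(scaled)) < 1e-6,
                 f"reported_percent {self.reported_percent} has more than "
                 f"{self.percent_decimals} decimal places")
        if self.numerator is not None:
            _require(isinstance(self.numerator, int) and self.numerator >= 0,
                     "numerator must be an integer >= 0")
            _require(self.numerator <= self.denominator,
                     "numerator must not exceed denominator")


@dataclass(frozen=True)
class SummaryStatClaim:
    """Reported summary statistics of one measurement (any subset present)."""

    n: Optional[int] = None
    mean: Optional[float] = None
    median: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None

    kind = "summary_stats"

    def __post_init__(self) -> None:
        if self.n is not None:
            _require(isinstance(self.n, int) and self.n >= 1, "n must be an integer >= 1")
        for name in ("mean", "median", "sd", "min", "max"):
            v = getattr(self, name)
            if v is not None:
                _require(_is_num(v), f"{name} must be a finite number")
        if self.min is not None and self.max is not None:
            _require(self.min <= self.max, "min must be <= max")


@dataclass(frozen=True)
class SumClaim:
    """Subgroup counts against a stated total.

    A before/after/change triple is encoded as ``parts=[after - before]``
    against ``stated_total=change``, hence signed integers are allowed.
    """

    parts: tuple
    stated_total: int

    kind = "sum"

    def __init__(self, parts: Sequence[int], stated_total: int):
        object.__setattr__(self, "parts", tuple(parts))
        object.__setattr__(self, "stated_total", stated_total)
        self.__post_init__()

    def __post_init__(self) -> None:
        _require(len(self.parts) > 0, "parts must be non-empty")
        _require(all(isinstance(p, int) for p in self.parts),
                 "parts must be integers")
        _require(isinstance(self.stated_total, int), "stated_total must be an integer")


@dataclass(frozen=True)
class TwoGroupClaim:
    """Two groups' mean/SD/n, with the text asserting comparability (or not)."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    asserted_comparable: bool = True

    kind = "two_group"

    def __post_init__(self) -> None:
        for name in ("mean1", "sd1", "mean2", "sd2"):
            _require(_is_num(getattr(self, name)), f"{name} must be a finite number")
        _require(self.sd1 >= 0 and self.sd2 >= 0, "standard deviations must be >= 0")
        _require(self.sd1 > 0 or self.sd2 > 0, "at least one sd must be positive")
        for name in ("n1", "n2"):
            n = getattr(self, name)
            _require(isinstance(n, int) and n >= 2, f"{name} must be an integer >= 2")
        _require(isinstance(self.asserted_comparable, bool),
                 "asserted_comparable must be boolean")


@dataclass(frozen=True)
class FactualPair:
    """The same quantity stated in two places, at a shared printed precision."""

    value_a: float
    value_b: float
    decimals: int
    location_a: str = ""
    location_b: str = ""

    kind = "factual"

    def __post_init__(self) -> None:
        _require(_is_num(self.value_a) and _is_num(self.value_b),
                 "values must be finite numbers")
        _require(isinstance(self.decimals, int) and self.decimals >= 0,
                 "decimals must be an integer >= 0")


NumericClaim = Union[PercentageClaim, SummaryStatClaim, SumClaim, TwoGroupClaim, FactualPair]

#: kind tag -> claim class, for deserialization and dispatch
CLAIM_KINDS = {
    cls.kind: cls
    for cls in (PercentageClaim, SummaryStatClaim, SumClaim, TwoGroupClaim, FactualPair)
}


@dataclass(frozen=True)
class CheckResult:
    """Outcome of one check applied to one claim."""

    category: str
    flagged: bool
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.category in CATEGORIES, f"unknown category {self.category!r}")
        if self.flagged:
            _require(bool(self.detail), "flagged result must carry a detail")


@dataclass
class ReportClaims:
    """All claims transcribed from one trial report, plus its covariates."""

    report_id: str
    claims: list
    retracted: Optional[bool] = None
    year: Optional[int] = None
    impact_factor: Optional[float] = None
    citations: Optional[int] = None
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        _require(isinstance(self.report_id, str) and self.report_id != "",
                 "report_id must be a non-empty string")
        if self.citations is not None:
            _require(isinstance(self.citations, int) and self.citations >= 0,
                     "citations must be an integer >= 0")


@dataclass
class ReportProfile:
    """Per-category and total discrepancy counts for one report."""

    report_id: str
    counts: dict
    total: int
    retracted: Optional[bool] = None
    year: Optional[int] = None
    impact_factor: Optional[float] = None
    citations: Optional[int] = None
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        _require(set(self.counts) == set(CATEGORIES),
                 "counts must cover exactly the six categories")
        _require(all(isinstance(v, int) and v >= 0 for v in self.counts.values()),
                 "counts must be non-negative integers")
        _require(self.total == sum(self.counts.values()),
                 "total must equal the sum of category counts")

    def to_row(self) -> dict:
        row = {"report_id": self.report_id}
        row.update({c: self.counts[c] for c in CATEGORIES})
        row["total"] = self.total
        for name in ("retracted", "year", "impact_factor", "citations", "pair_id"):
            row[name] = getattr(self, name)
        return row
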