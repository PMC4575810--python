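"""Readers/writers for the claims and profiles formats, and run configuration.

Two interchangeable claim encodings are supported:

* JSON — a list of report objects, each with covariates and a ``claims``
  array whose entries are discriminated by a ``kind`` field
  (``percentage``, ``summary_stats``, ``sum``, ``two_group``,
  ``factual``).
* CSV — one claim per row, report-level columns repeated, unused claim
  columns empty. UTF-8, comma separator, decimal point, header required.
  ``parts`` is semicolon-joined.

Parsers validate on construction and report the offending report/row and
field; out-of-domain values are rejected, never silently coerced
(percentages above 100 are legal claims and left to the checks).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .claims import (
    CATEGORIES,
    CLAIM_KINDS,
    CheckResult,
    InvalidClaimError,
    ReportClaims,
    ReportProfile,
    SumClaim,
)

__all__ = [
    "SchemaError",
    "RunConfig",
    "claim_to_dict",
    "claim_from_dict",
    "read_claims",
    "write_claims",
    "read_profiles",
    "write_profiles",
    "profiles_to_frame",
]

REPORT_FIELDS = ("report_id", "retracted", "year", "impact_factor", "citations", "pair_id")

#: flat CSV columns for each claim kind
_CSV_CLAIM_COLUMNS = [
    "kind",
    "numerator", "denominator", "reported_percent", "percent_decimals",
    "n", "mean", "median", "sd", "min", "max",
    "parts", "stated_total",
    "mean1", "sd1", "n1", "mean2", "sd2", "n2", "asserted_comparable",
    "value_a", "value_b", "decimals", "location_a", "location_b",
]

_INT_FIELDS = {"numerator", "denominator", "percent_decimals", "n", "stated_total",
               "n1", "n2", "decimals", "year", "citations"}
_BOOL_FIELDS = {"asserted_comparable", "retracted"}


class SchemaError(ValueError):
    """A claims or profiles file violates the documented schema."""


def claim_to_dict(claim) -> dict:
    d = {"kind": claim.kind}
    d.update(asdict(claim))
    if isinstance(claim, SumClaim):
        d["parts"] = list(claim.parts)
    return d


def _coerce(field: str, value, where: str):
    if value is None:
        return None
    if field in _BOOL_FIELDS:
        if isinstance(value, bool):
            return value
        raise SchemaError(f"{where}: field {field!r} must be boolean, got {value!r}")
    if field in _INT_FIELDS:
        if isinstance(value, int) and not isinstance(value, bool):
            return value
        if isinstance(value, float) and value.is_integer():
            return int(value)
        raise SchemaError(f"{where}: field {field!r} must be an integer, got {value!r}")
    return value


def claim_from_dict(d: dict, where: str = "claim"):
    if "kind" not in d:
        raise SchemaError(f"{where}: missing 'kind' field")
    kind = d["kind"]
    cls = CLAIM_KINDS.get(kind)
    if cls is None:
        raise SchemaError(f"{where}: unknown claim kind {kind!r}")
    names = {f.name for f in dataclasses.fields(cls)}
    extra = set(d) - names - {"kind"}
    if extra:
        raise SchemaError(f"{where}: unexpected fields {sorted(extra)} for kind {kind!r}")
    kwargs = {k: _coerce(k, v, where) for k, v in d.items() if k != "kind"}
    if cls is SumClaim and "parts" in kwargs and kwargs["parts"] is not None:
        kwargs["parts"] = [_coerce("stated_total", p, where) for p in kwargs["parts"]]
    try:
        return cls(**kwargs)
    except (TypeError, InvalidClaimError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def _report_from_dict(d: dict, where: str) -> ReportClaims:
    if "report_id" not in d:
        raise SchemaError(f"{where}: missing 'report_id'")
    claims = [
        claim_from_dict(c, f"{where}, claim {i}")
        for i, c in enumerate(d.get("claims", []))
    ]
    kwargs = {k: _coerce(k, d.get(k), where) for k in REPORT_FIELDS}
    try:
        return ReportClaims(claims=claims, **kwargs)
    except InvalidClaimError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def read_claims(path, format: Optional[str] = None) -> List[ReportClaims]:
    """Read a claims file (JSON or CSV, inferred from the extension)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
        if not isinstance(data, list):
            raise SchemaError(f"{path}: top level must be a list of reports")
        reports = [_report_from_dict(d, f"{path} report {i}") for i, d in enumerate(data)]
    elif fmt == "csv":
        reports = _read_claims_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    seen = set()
    for r in reports:
        if r.report_id in seen:
            raise SchemaError(f"{path}: duplicate report_id {r.report_id!r}")
        seen.add(r.report_id)
    return reports


def write_claims(reports: Sequence[ReportClaims], path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        data = []
        for r in reports:
            d = {k: getattr(r, k) for k in REPORT_FIELDS}
            d["claims"] = [claim_to_dict(c) for c in r.claims]
            data.append(d)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)
            fh.write("\n")
    elif fmt == "csv":
        _write_claims_csv(reports, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_claims_csv(reports: Sequence[ReportClaims], path) -> None:
    rows = []
    for r in reports:
        base = {k: getattr(r, k) for k in REPORT_FIELDS}
        for c in r.claims:
            row = dict.fromkeys(_CSV_CLAIM_COLUMNS)
            row.update(base)
            row.update(claim_to_dict(c))
            if isinstance(c, SumClaim):
                row["parts"] = ";".join(str(p) for p in c.parts)
            rows.append(row)
    cols = list(REPORT_FIELDS) + _CSV_CLAIM_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _cell(row, col, where):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if col in _BOOL_FIELDS:
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0"):
            return True
        if s in ("false", "0", "0.0"):
            return False
        raise SchemaError(f"{where}: field {col!r} must be boolean, got {v!r}")
    if col in _INT_FIELDS:
        try:
            f = float(v)
        except ValueError:
            raise SchemaError(f"{where}: field {col!r} must be an integer, got {v!r}")
        if not f.is_integer():
            raise SchemaError(f"{where}: field {col!r} must be an integer, got {v!r}")
        return int(f)
    if col in ("location_a", "location_b", "report_id", "pair_id", "kind"):
        return str(v)
    try:
        return float(v)
    except ValueError:
        raise SchemaError(f"{where}: field {col!r} must be numeric, got {v!r}")


def _read_claims_csv(path) -> List[ReportClaims]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"report_id", "kind"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    by_report: dict = {}
    order: list = []
    for idx, raw in df.iterrows():
        where = f"{path} row {idx + 2}"  # 1-based + header
        row = raw.to_dict()
        kind = row.get("kind", "")
        cls = CLAIM_KINDS.get(kind)
        if cls is None:
            raise SchemaError(f"{where}: unknown claim kind {kind!r}")
        names = {f.name for f in dataclasses.fields(cls)}
        d = {"kind": kind}
        for name in names:
            if name == "parts":
                s = row.get("parts", "")
                if s == "":
                    raise SchemaError(f"{where}: missing field 'parts'")
                try:
                    d["parts"] = [int(p) for p in str(s).split(";")]
                except ValueError:
                    raise SchemaError(f"{where}: malformed 'parts' {s!r}")
            else:
                d[name] = _cell(row, name, where)
        claim = claim_from_dict(d, where)
        rid = str(row["report_id"])
        if rid not in by_report:
            meta = {k: _cell(row, k, where) for k in REPORT_FIELDS if k != "report_id"}
            by_report[rid] = ReportClaims(report_id=rid, claims=[], **meta)
            order.append(rid)
        by_report[rid].claims.append(claim)
    return [by_report[r] for r in order]


# ---------------------------------------------------------------------------
# profiles

def profiles_to_frame(profiles: Sequence[ReportProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in profiles])


def write_profiles(profiles: Sequence[ReportProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> List[ReportProfile]:
    df = pd.read_csv(path)
    required = {"report_id", *CATEGORIES, "total"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing profile columns {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        where = f"{path} row {idx + 2}"
        counts = {c: int(row[c]) for c in CATEGORIES}
        meta = {}
        for k in REPORT_FIELDS:
            if k == "report_id":
                continue
            v = row.get(k)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                meta[k] = None
            elif k in _BOOL_FIELDS:
                meta[k] = bool(v) if isinstance(v, (bool,)) else str(v).lower() in ("true", "1", "1.0")
            elif k in _INT_FIELDS:
                meta[k] = int(float(v))
            elif k == "pair_id":
                meta[k] = str(v)
            else:
                meta[k] = float(v)
        try:
            out.append(ReportProfile(report_id=str(row["report_id"]), counts=counts,
                                     total=int(row["total"]), **meta))
        except InvalidClaimError as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable to JSON."""

    rounding: str = "either"  # half_up | half_even | either
    ttest: str = "welch"  # welch | pooled
    alpha: float = 0.05
    level: float = 0.95
    zero_method: str = "drop"  # wilcoxon zero differences: drop | pratt
    quartiles: str = "linear"  # interpolating convention (fixed)
    zinb_maxiter: int = 2000
    zinb_gtol: float = 1e-8
    covariates: tuple = ("retraction",)
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.rounding not in ("either", "half_up", "half_even"):
            raise ValueError(f"invalid rounding {self.rounding!r}")
        if self.ttest not in ("welch", "pooled"):
            raise ValueError(f"invalid ttest {self.ttest!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.zero_method not in ("drop", "pratt"):
            raise ValueError(f"invalid zero_method {self.zero_method!r}")
        if self.quartiles != "linear":
            raise ValueError("only the linear quartile convention is implemented")
        self.covariates = tuple(self.covariates)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))
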