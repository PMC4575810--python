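"""Blinded case-control analysis of per-report discrepancy counts.

Given one discrepancy-count profile per report, with retraction status
as the case label and reports paired within journal, this module
provides the study's statistical toolkit:

* paired Wilcoxon signed-rank comparison of counts (exact null
  distribution with midranked ties for small samples);
* 2x2 odds ratios with Woolf (log-OR normal) confidence intervals and
  the Haldane–Anscombe +0.5 correction for zero cells;
* zero-inflated negative binomial (NB2) regression of counts on
  retraction status and report covariates, reported as incidence rate
  ratios (count component) and odds ratios (excess-zero component);
* sensitivity/specificity of retraction detection over all count
  thresholds, with the odds ratio above each threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

from .claims import CATEGORIES, ReportProfile

__all__ = [
    "TwoByTwo",
    "ORResult",
    "WilcoxonResult",
    "CoefEstimate",
    "ZINBFit",
    "DegenerateDataError",
    "ConvergenceError",
    "odds_ratio_ci",
    "paired_wilcoxon",
    "prevalence_table",
    "fit_zinb",
    "threshold_performance",
    "summarize_pairs",
    "per_category_tests",
    "paired_totals",
]

ZINB_COVARIATES = ("retraction", "year", "impact_factor", "citations")


class DegenerateDataError(ValueError):
    """The data carry no information for the requested analysis."""


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge after all restarts."""


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table oriented so that OR > 1 means exposure predicts case status.

    a: exposed cases, b: unexposed cases, c: exposed controls,
    d: unexposed controls. In this study: a = retracted reports with a
    discrepancy, b = retracted without, c = unretracted with,
    d = unretracted without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float
    p: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-) over nonzero differences
    p: float
    n_nonzero: int
    method: str  # "exact" or "normal"


def odds_ratio_ci(table: TwoByTwo, level: float = 0.95) -> ORResult:
    """Odds ratio with Woolf confidence interval and z-test p-value.

    The +0.5 Haldane–Anscombe correction is applied to every cell when
    any cell is zero. A table with an empty margin has no defined OR.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateDataError("odds ratio undefined: an entire margin is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return ORResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        level=level,
        p=float(p),
        corrected=corrected,
    )


def _signed_rank_stats(diffs: np.ndarray) -> Tuple[float, float, np.ndarray]:
    ranks = stats.rankdata(np.abs(diffs))  # midranks for ties
    w_pos = float(ranks[diffs > 0].sum())
    w_neg = float(ranks[diffs < 0].sum())
    return w_pos, w_neg, ranks

def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p via dynamic programming over doubled midranks.

    Doubling makes midranks (integers or half-integers) integral, so the
    null distribution of 2*W+ under random signs is a convolution of
    m two-point distributions, computed exactly.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    dist = np.zeros(doubled.sum() + 1)
    dist[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(dist)
        shifted[d:] = dist[: dist.size - d]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_obs))
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def paired_wilcoxon(
    pairs: Sequence[Tuple[float, float]],
    zero_method: str = "drop",
    mode: str = "auto",
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on per-pair count differences.

    Differences are retracted minus unretracted. Zero differences are
    dropped by default (``zero_method="pratt"`` keeps them in the
    ranking). The exact null distribution (valid with midranked ties) is
    used for up to ``exact_limit`` nonzero pairs, a tie-corrected normal
    approximation beyond.
    """
    if zero_method not in ("drop", "pratt"):
        raise ValueError("zero_method must be 'drop' or 'pratt'")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError("mode must be 'auto', 'exact' or 'normal'")
    diffs = np.asarray([r - u for r, u in pairs], dtype=float)
    nonzero = diffs[diffs != 0]
    m = nonzero.size
    if m == 0:
        raise DegenerateDataError("all paired differences are zero")

    if zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(diffs))
        ranks = ranks_all[diffs != 0]
    else:
        ranks = stats.rankdata(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    w_neg = float(ranks[nonzero < 0].sum())
    statistic = min(w_pos, w_neg)

    use_exact = mode == "exact" or (mode == "auto" and m <= exact_limit)
    if use_exact:
        p = _exact_signed_rank_p(ranks, statistic)
        method = "exact"
    else:
        mean = ranks.sum() / 2.0
        var = float(np.square(ranks).sum()) / 4.0
        z = (w_pos - mean) / np.sqrt(var)
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(statistic=statistic, p=p, n_nonzero=m, method=method)


def prevalence_table(profiles: Sequence[ReportProfile]) -> TwoByTwo:
    """2x2 of discrepancy presence (total >= 1) by retraction status."""
    a = b = c = d = 0
    for p in profiles:
        if p.retracted is None:
            raise ValueError(f"report {p.report_id!r} has no retraction label")
        if p.retracted:
            a, b = (a + 1, b) if p.total >= 1 else (a, b + 1)
        else:
            c, d = (c + 1, d) if p.total >= 1 else (c, d + 1)
    return TwoByTwo(a, b, c, d)


@dataclass(frozen=True)
class CoefEstimate:
    """One exponentiated regression coefficient (IRR or OR) with Wald CI."""

    name: str
    ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


@dataclass
class ZINBFit:
    """Fitted zero-inflated NB2 model.

    ``count_component`` holds incidence rate ratios (log link),
    ``zero_component`` odds ratios for an excess structural zero
    (logit link), both keyed by covariate name with "intercept" first.
    ``dispersion`` is the NB2 size theta (variance = mu + mu^2/theta).
    """

    count_component: dict
    zero_component: dict
    log_likelihood: float
    converged: bool
    dispersion: float
    n_obs: int
    level: float = 0.95
    separation_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, ests in (("count", self.count_component),
                           ("zero", self.zero_component)):
            for est in ests.values():
                rows.append({
                    "component": comp, "term": est.name, "ratio": est.ratio,
                    "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
                })
        return pd.DataFrame(rows)


def _design_matrix(profiles: Sequence[ReportProfile], covariates: Sequence[str]):
    cols = {}
    for name in covariates:
        if name not in ZINB_COVARIATES:
            raise ValueError(f"unknown covariate {name!r}; choose from {ZINB_COVARIATES}")
        attr = "retracted" if name == "retraction" else name
        vals = []
        for p in profiles:
            v = getattr(p, attr)
            if v is None:
                raise ValueError(f"report {p.report_id!r} lacks covariate {name!r}")
            vals.append(float(v))
        col = np.asarray(vals)
        if name == "year":
            col = col - col.mean()  # centered: stabilizes the intercept
        cols[name] = col
    X = np.column_stack([np.ones(len(profiles))] + [cols[n] for n in covariates])
    return X, ["intercept", *covariates]


def fit_zinb(
    profiles: Sequence[ReportProfile],
    covariates: Sequence[str] = ("retraction",),
    level: float = 0.95,
    maxiter: int = 2000,
    gtol: float = 1e-8,
) -> ZINBFit:
    """Zero-inflated NB2 regression of total discrepancy counts.

    The count mean uses a log link and the excess-zero probability a
    logit link, both on the same covariates. Coefficients are returned
    exponentiated (IRRs for the count component, ORs for the zero
    component) with Wald intervals. The fit is attempted from several
    starting points and refuses to return silently when none converges.
    """
    if len(profiles) < 10:
        raise ValueError("at least 10 profiles are required to fit the model")
    y = np.asarray([p.total for p in profiles], dtype=float)
    if y.max() == 0:
        raise DegenerateDataError("all counts are zero; nothing to model")
    X, names = _design_matrix(profiles, covariates)
    model = ZeroInflatedNegativeBinomialP(y, X, exog_infl=X, p=2)

    k = X.shape[1]
    # start params: [inflate (k), count (k), alpha]
    naive = np.r_[np.zeros(k), np.log(max(y.mean(), 0.1)), np.zeros(k - 1), 1.0]
    attempts = [
        {"start_params": None, "method": "bfgs"},
        {"start_params": naive, "method": "bfgs"},
        {"start_params": naive, "method": "nm"},
    ]
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for att in attempts:
            try:
                cand = model.fit(start_params=att["start_params"],
                                 method=att["method"], maxiter=maxiter,
                                 gtol=gtol, disp=0)
            except Exception:
                continue
            ok = (cand.mle_retvals.get("converged", False)
                  and np.all(np.isfinite(cand.params))
                  and np.all(np.isfinite(cand.bse)))
            if ok:
                res = cand
                break
            if res is None and np.all(np.isfinite(cand.params)):
                res = cand  # keep best-effort candidate for diagnostics
    if res is None or not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "zero-inflated NB fit did not converge after restarts; "
            f"diagnostics: {None if res is None else res.mle_retvals}")

    params, bse = np.asarray(res.params), np.asarray(res.bse)
    separation = bool(np.any(bse[:k] > 25))  # zero component blown up
    if separation:
        warnings.warn("possible separation in the excess-zero component; "
                      "its confidence intervals are unreliable", RuntimeWarning,
                      stacklevel=2)
    z = stats.norm.ppf(0.5 + level / 2)

    def comp(offset: int) -> dict:
        out = {}
        for i, name in enumerate(names):
            b, s = params[offset + i], bse[offset + i]
            out[name] = CoefEstimate(
                name=name, ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * s)), ci_high=float(np.exp(b + z * s)),
                p=float(2 * stats.norm.sf(abs(b) / s)) if s > 0 else float("nan"),
                coef=float(b), se=float(s),
            )
        return out

    alpha = float(params[-1])
    return ZINBFit(
        count_component=comp(k),
        zero_component=comp(0),
        log_likelihood=float(res.llf),
        converged=True,
        dispersion=float(1.0 / alpha) if alpha > 0 else float("inf"),
        n_obs=len(profiles),
        level=level,
        separation_warning=separation,
    )


def _split_totals(profiles: Sequence[ReportProfile]):
    retr = np.asarray([p.total for p in profiles if p.retracted], dtype=int)
    unretr = np.asarray([p.total for p in profiles if p.retracted is False], dtype=int)
    if retr.size == 0 or unretr.size == 0:
        raise DegenerateDataError("need both retracted and unretracted profiles")
    return retr, unretr


def threshold_performance(profiles: Sequence[ReportProfile]) -> pd.DataFrame:
    """Sensitivity/specificity of retraction detection over count thresholds.

    For each threshold k from 0 to max(total)+1, a report is called
    retracted when its total is >= k. Sensitivity is the fraction of
    retracted reports so called; specificity the fraction of unretracted
    reports not called. The odds ratio comes from the induced 2x2 (with
    the zero-cell correction where needed).
    """
    retr, unretr = _split_totals(profiles)
    rows = []
    kmax = int(max(retr.max(), unretr.max())) + 1
    for k in range(kmax + 1):
        a = int((retr >= k).sum())
        b = retr.size - a
        c = int((unretr >= k).sum())
        d = unretr.size - c
        try:
            or_ = odds_ratio_ci(TwoByTwo(a, b, c, d)).odds_ratio
        except DegenerateDataError:
            or_ = np.nan
        rows.append({
            "threshold": k,
            "sensitivity": a / retr.size,
            "specificity": d / unretr.size,
            "odds_ratio": or_,
        })
    return pd.DataFrame(rows)


def _median_iqr(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(x.min()), "max": float(x.max())}


def summarize_pairs(profiles: Sequence[ReportProfile]) -> dict:
    """Arm-level summary: totals, fold ratio, medians/IQRs, category totals.

    The fold ratio is the retracted-arm discrepancy total over the
    unretracted-arm total (None when the unretracted total is zero).
    Quartiles interpolate linearly between order statistics.
    """
    retr, unretr = _split_totals(profiles)
    total_r, total_u = int(retr.sum()), int(unretr.sum())
    by_cat = {
        cat: {
            "retracted": int(sum(p.counts[cat] for p in profiles if p.retracted)),
            "unretracted": int(sum(p.counts[cat] for p in profiles if p.retracted is False)),
        }
        for cat in CATEGORIES
    }
    return {
        "n_retracted": int(retr.size),
        "n_unretracted": int(unretr.size),
        "total_retracted": total_r,
        "total_unretracted": total_u,
        "fold_ratio": (total_r / total_u) if total_u > 0 else None,
        "retracted": _median_iqr(retr),
        "unretracted": _median_iqr(unretr),
        "category_totals": by_cat,
    }


def paired_totals(profiles: Sequence[ReportProfile], category: Optional[str] = None):
    """(retracted_total, unretracted_total) per journal pair.

    Uses ``pair_id`` to match reports; every pair must contain exactly
    one retracted and one unretracted report.
    """
    by_pair = {}
    for p in profiles:
        if p.pair_id is None:
            raise ValueError(f"report {p.report_id!r} has no pair_id")
        by_pair.setdefault(p.pair_id, []).append(p)
    pairs = []
    for pid in sorted(by_pair):
        members = by_pair[pid]
        if len(members) != 2 or sum(bool(m.retracted) for m in members) != 1:
            raise ValueError(f"pair {pid!r} is not one retracted + one unretracted report")
        r = next(m for m in members if m.retracted)
        u = next(m for m in members if not m.retracted)
        if category is None:
            pairs.append((r.total, u.total))
        else:
            pairs.append((r.counts[category], u.counts[category]))
    return pairs


def per_category_tests(
    profiles: Sequence[ReportProfile],
    zero_method: str = "drop",
    holm: bool = False,
) -> pd.DataFrame:
    """Paired Wilcoxon per category, with per-arm median (IQR, range).

    Raw p values are reported (set ``holm=True`` for an additional
    Holm-adjusted column). A category with all-zero differences yields
    a NaN p and a "degenerate" note.
    """
    rows = []
    for cat in CATEGORIES:
        retr = np.asarray([p.counts[cat] for p in profiles if p.retracted], dtype=float)
        unretr = np.asarray([p.counts[cat] for p in profiles if p.retracted is False],
                            dtype=float)
        row = {"category": cat}
        for arm, x in (("retracted", retr), ("unretracted", unretr)):
            s = _median_iqr(x)
            row.update({f"{arm}_{k}": v for k, v in s.items()})
        try:
            res = paired_wilcoxon(paired_totals(profiles, cat), zero_method=zero_method)
            row.update({"statistic": res.statistic, "p": res.p,
                        "n_nonzero": res.n_nonzero, "note": ""})
        except DegenerateDataError:
            row.update({"statistic": np.nan, "p": np.nan, "n_nonzero": 0,
                        "note": "degenerate: all paired differences zero"})
        rows.append(row)
    out = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="holm")[1]
        out["p_holm"] = adj
    return out
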