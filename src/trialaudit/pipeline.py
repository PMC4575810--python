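"""End-to-end composition: claims -> audit -> case-control analysis bundle."""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .casecontrol import (
    ConvergenceError,
    DegenerateDataError,
    fit_zinb,
    odds_ratio_ci,
    paired_totals,
    paired_wilcoxon,
    per_category_tests,
    prevalence_table,
    summarize_pairs,
    threshold_performance,
)
from .checks import audit_report, check_claims
from .claims import ReportClaims, ReportProfile
from .io import RunConfig, profiles_to_frame, read_claims, write_profiles

__all__ = ["audit_reports", "analyze_profiles", "run_pipeline"]


def audit_reports(reports: Sequence[ReportClaims], config: RunConfig):
    """Audit every report; returns (profiles, per-claim results)."""
    profiles, results = [], {}
    for rep in reports:
        profiles.append(audit_report(rep, alpha=config.alpha,
                                     rounding=config.rounding, ttest=config.ttest))
        results[rep.report_id] = [
            dataclasses.asdict(r)
            for r in check_claims(rep, alpha=config.alpha,
                                  rounding=config.rounding, ttest=config.ttest)
        ]
    return profiles, results


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def analyze_profiles(profiles: Sequence[ReportProfile], config: RunConfig) -> dict:
    """The case-control analyses that the profiles support.

    Always computes the arm summary and threshold sweep; adds the 2x2
    odds ratio, paired Wilcoxon tests and the ZINB fit when labels,
    pairing and covariates are available. Skipped or degenerate stages
    are recorded, not silently dropped.
    """
    out: dict = {"skipped": {}}
    labeled = all(p.retracted is not None for p in profiles)
    if not labeled:
        out["skipped"]["all"] = "profiles lack retraction labels"
        return out

    out["summary"] = summarize_pairs(profiles)
    out["threshold_performance"] = threshold_performance(profiles).to_dict("records")
    try:
        orr = odds_ratio_ci(prevalence_table(profiles), level=config.level)
        out["prevalence_odds_ratio"] = dataclasses.asdict(orr)
    except DegenerateDataError as exc:
        out["skipped"]["prevalence_odds_ratio"] = str(exc)

    if all(p.pair_id is not None for p in profiles):
        try:
            w = paired_wilcoxon(paired_totals(profiles), zero_method=config.zero_method)
            out["wilcoxon_total"] = dataclasses.asdict(w)
        except (DegenerateDataError, ValueError) as exc:
            out["skipped"]["wilcoxon_total"] = str(exc)
        try:
            out["per_category"] = per_category_tests(
                profiles, zero_method=config.zero_method).to_dict("records")
        except ValueError as exc:
            out["skipped"]["per_category"] = str(exc)
    else:
        out["skipped"]["wilcoxon_total"] = "profiles lack pair_id"

    attr = {"retraction": "retracted"}
    usable = [c for c in config.covariates
              if all(getattr(p, attr.get(c, c)) is not None for p in profiles)]
    if usable:
        try:
            fit = fit_zinb(profiles, covariates=usable, level=config.level,
                           maxiter=config.zinb_maxiter, gtol=config.zinb_gtol)
            out["zinb"] = {
                "count_component": {k: dataclasses.asdict(v)
                                    for k, v in fit.count_component.items()},
                "zero_component": {k: dataclasses.asdict(v)
                                   for k, v in fit.zero_component.items()},
                "log_likelihood": fit.log_likelihood,
                "dispersion": fit.dispersion,
                "converged": fit.converged,
                "covariates": list(usable),
            }
        except (ConvergenceError, DegenerateDataError, ValueError) as exc:
            out["skipped"]["zinb"] = str(exc)
    else:
        out["skipped"]["zinb"] = "no usable covariates"
    return _jsonable(out)


def run_pipeline(config: RunConfig, claims_path) -> dict:
    """Read claims, audit, analyze, and write the full output bundle.

    Writes into ``config.out_dir``: profiles.csv, check_results.json,
    analysis.json, threshold.csv, zinb.csv (when fitted) and run_log.json
    (config, package/python versions, seed). Identical config and input
    produce identical outputs. Raises before writing anything when the
    claims file is empty or invalid.
    """
    reports = read_claims(claims_path)
    if not reports:
        raise ValueError(f"{claims_path}: no reports found")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profiles, results = audit_reports(reports, config)
    analysis = analyze_profiles(profiles, config)

    write_profiles(profiles, out_dir / "profiles.csv")
    with open(out_dir / "check_results.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=1)
    with open(out_dir / "analysis.json", "w", encoding="utf-8") as fh:
        json.dump(analysis, fh, indent=1)
    if "threshold_performance" in analysis:
        pd.DataFrame(analysis["threshold_performance"]).to_csv(
            out_dir / "threshold.csv", index=False)
    if "zinb" in analysis:
        rows = []
        for comp in ("count_component", "zero_component"):
            for term, est in analysis["zinb"][comp].items():
                rows.append({"component": comp.replace("_component", ""), **est})
        pd.DataFrame(rows).to_csv(out_dir / "zinb.csv", index=False)
    log = {
        "config": {**dataclasses.asdict(config), "covariates": list(config.covariates)},
        "trialaudit_version": __version__,
        "python_version": platform.python_version(),
        "n_reports": len(reports),
        "claims_path": str(claims_path),
    }
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1)
    return {"profiles": profiles, "check_results": results, "analysis": analysis,
            "out_dir": str(out_dir)}
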