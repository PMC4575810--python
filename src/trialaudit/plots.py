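"""Plots mirroring the study's figures (paired bars, category totals, ROC-style sweep)."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .claims import CATEGORIES, ReportProfile
from .casecontrol import summarize_pairs, threshold_performance

__all__ = ["plot_paired_counts", "plot_category_totals", "plot_threshold_curve"]


def plot_paired_counts(profiles: Sequence[ReportProfile], path: Optional[str] = None):
    """Back-to-back bars: one row per journal pair, unretracted left, retracted right."""
    pairs = {}
    for p in profiles:
        pairs.setdefault(p.pair_id, {})["r" if p.retracted else "u"] = p.total
    rows = sorted(pairs.values(), key=lambda d: d.get("r", 0) + d.get("u", 0))
    y = np.arange(len(rows))
    fig, ax = plt.subplots(figsize=(6, max(3, len(rows) * 0.12)))
    ax.barh(y, [d.get("r", 0) for d in rows], color="firebrick", label="retracted")
    ax.barh(y, [-d.get("u", 0) for d in rows], color="steelblue", label="unretracted")
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("discrepancy count")
    ax.set_ylabel("journal pair")
    ax.legend(frameon=False)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_category_totals(profiles: Sequence[ReportProfile], path: Optional[str] = None):
    """Total discrepancies per category, retracted vs unretracted arm."""
    s = summarize_pairs(profiles)["category_totals"]
    x = np.arange(len(CATEGORIES))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - 0.2, [s[c]["unretracted"] for c in CATEGORIES], 0.4,
           color="steelblue", label="unretracted")
    ax.bar(x + 0.2, [s[c]["retracted"] for c in CATEGORIES], 0.4,
           color="firebrick", label="retracted")
    ax.set_xticks(x, [c.replace("_", "\n") for c in CATEGORIES], fontsize=8)
    ax.set_ylabel("total discrepancies")
    ax.legend(frameon=False)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_threshold_curve(profiles: Sequence[ReportProfile], path: Optional[str] = None):
    """Sensitivity and specificity of retraction detection vs count threshold."""
    perf = threshold_performance(profiles)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(perf["threshold"], perf["sensitivity"], where="post", label="sensitivity")
    ax.step(perf["threshold"], perf["specificity"], where="post", label="specificity")
    ax.set_xlabel("discrepancy count threshold (flag if total ≥ threshold)")
    ax.set_ylabel("proportion")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
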