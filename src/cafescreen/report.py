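"""Cohort analysis report: group comparisons and screener correlations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import CafeScreenError, DegenerateInputError, SampleSizeError
from .stats import StatResult, fisher_exact, pearson_r, summarize_cohort, welch_t

__all__ = ["CohortAnalysis", "analyze_cohort", "render_report"]

SUMMARY_FIELDS = (
    "grand_total",
    "immediate_total",
    "delayed_total",
    "recognition_total",
    "spatial_combined_total",
    "levels_played",
    "total_minutes",
    "screener_score",
)


@dataclass
class CohortAnalysis:
    """Everything the text report and summary CSV are rendered from."""

    summary: pd.DataFrame
    group_tests: dict[str, StatResult | str] = field(default_factory=dict)
    impairment_fisher: Optional[StatResult | str] = None
    correlations: dict[str, StatResult | str] = field(default_factory=dict)
    n_tests: int = 0


def _safe(fn, *args):
    try:
        return fn(*args)
    except (DegenerateInputError, SampleSizeError, CafeScreenError) as exc:
        return f"not computed ({exc})"


def analyze_cohort(table: pd.DataFrame) -> CohortAnalysis:
    """Run the validation statistics over a cohort table.

    Produces group summaries for the score fields present, Welch
    t-tests younger-vs-older on the continuous scores, a Fisher exact
    test on the impairment flag by group, and Pearson correlations of
    the module totals with the reference-screener score.  Degenerate
    inputs (tiny or constant groups) are reported as not-computed
    entries rather than aborting the run.
    """
    fields = [f for f in SUMMARY_FIELDS if f in table.columns]
    summary = summarize_cohort(table, fields, by_group=True)
    young = table[table["group"] == "younger"]
    old = table[table["group"] == "older"]
    analysis = CohortAnalysis(summary=summary)

    for f in ("grand_total", "screener_score", "total_minutes"):
        if f in table.columns:
            analysis.group_tests[f] = _safe(
                welch_t, young[f].to_numpy(), old[f].to_numpy()
            )
            analysis.n_tests += 1

    if "impaired_flag" in table.columns:
        a = int(young["impaired_flag"].sum())
        b = int((~young["impaired_flag"].astype(bool)).sum())
        c = int(old["impaired_flag"].sum())
        d = int((~old["impaired_flag"].astype(bool)).sum())
        analysis.impairment_fisher = _safe(fisher_exact, a, b, c, d)
        analysis.n_tests += 1

    if "screener_score" in table.columns:
        for f in ("grand_total", "immediate_total", "delayed_total", "recognition_total"):
            if f in table.columns:
                analysis.correlations[f] = _safe(
                    pearson_r, table[f].to_numpy(), table["screener_score"].to_numpy()
                )
                analysis.n_tests += 1
    return analysis


def _fmt(res: StatResult | str, label: str) -> str:
    if isinstance(res, str):
        return f"  {label}: {res}"
    df = f", df={res.df:.1f}" if res.df is not None and res.df == res.df else ""
    return f"  {label}: stat={res.statistic:.4f}{df}, p={res.p_value:.4g}, n={res.n}"


def render_report(analysis: CohortAnalysis) -> str:
    """Human-readable text report of a cohort analysis."""
    lines = ["Cohort analysis report", "=" * 22, "", "Group summaries (mean/SD/range):"]
    for _, row in analysis.summary.iterrows():
        lines.append(
            f"  {row['field']:<24s} {row['group']:<8s} n={row['n']:<4d} "
            f"mean={row['mean']:.2f} sd={row['sd']:.2f} "
            f"range={row['min']:.1f}-{row['max']:.1f}"
        )
    lines += ["", "Group comparisons (Welch t, younger vs older):"]
    for f, res in analysis.group_tests.items():
        lines.append(_fmt(res, f))
    if analysis.impairment_fisher is not None:
        lines += ["", "Impairment flag by group (Fisher exact):"]
        lines.append(_fmt(analysis.impairment_fisher, "impaired_flag"))
    lines += ["", "Correlation with reference screener (Pearson r):"]
    for f, res in analysis.correlations.items():
        lines.append(_fmt(res, f))
    lines += [
        "",
        f"{analysis.n_tests} statistical tests were run; no multiple-testing "
        "correction was applied.",
    ]
    return "\n".join(lines) + "\n"
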