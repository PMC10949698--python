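"""Validation statistics over cohort tables.

The screening-validation pipeline compares a simulated (or imported)
cohort's module scores against a reference screener: group summaries in
the usual mean [SD], range report shape; Welch two-sample t-tests for
continuous group differences; Fisher's exact test for 2x2 categorical
comparisons; Pearson correlations between module and screener scores;
and Cohen's kappa with the conventional agreement bands (0.8-1.0 almost
perfect, 0.6-0.8 substantial, 0.4-0.6 moderate, 0.2-0.4 fair).

Implementation notes: the two-sample t-test is Welch's (unequal
variances) — the safer default with unequal group sizes; Fisher's
two-sided p follows the "small-p" convention (sum of all
margin-consistent table probabilities no larger than the observed
one); kappa band boundaries are half-open upward, so 0.8 is already
"almost perfect".  No multiple-testing correction is applied; reports
annotate how many tests were run instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .errors import DegenerateInputError, PointRangeError, SampleSizeError, SchemaError

__all__ = [
    "StatResult",
    "summarize_cohort",
    "pearson_r",
    "welch_t",
    "fisher_exact",
    "cohen_kappa",
    "kappa_band",
    "KAPPA_BANDS",
]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its p-value and sample sizes."""

    statistic: float
    p_value: float
    df: Optional[float] = None
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise PointRangeError(f"p-value {self.p_value} outside [0, 1]")


def summarize_cohort(
    table: pd.DataFrame,
    fields: Sequence[str],
    by_group: bool = True,
) -> pd.DataFrame:
    """Mean, SD, range and counts per field, overall and per group.

    Returns one row per (field, group) with ``group`` = ``all`` for the
    overall row, in the familiar cohort-table report shape.
    """
    missing = [f for f in fields if f not in table.columns]
    if missing:
        raise SchemaError(f"unknown field(s) in cohort table: {missing}")
    slices: list[tuple[str, pd.DataFrame]] = [("all", table)]
    if by_group and "group" in table.columns:
        slices += [(g, sub) for g, sub in table.groupby("group", sort=True)]
    rows = []
    for field in fields:
        for name, sub in slices:
            x = pd.to_numeric(sub[field])
            n = int(x.notna().sum())
            rows.append(
                {
                    "field": field,
                    "group": name,
                    "n": n,
                    "pct": 100.0 * n / len(table) if len(table) else float("nan"),
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)) if n > 1 else float("nan"),
                    "min": float(x.min()),
                    "max": float(x.max()),
                }
            )
    return pd.DataFrame(rows)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson product-moment correlation with a two-sided p-value.

    The p-value comes from the t transform ``r * sqrt((n-2)/(1-r^2))``
    on ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SampleSizeError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise SampleSizeError(f"Pearson correlation needs n >= 3, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("Pearson correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(n - 2), n=(n,))


def welch_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Welch two-sample t-test (unequal variances), two-sided.

    When both groups are constant the statistic degenerates: equal
    means give t = 0, p = 1; different means give a signed infinite
    statistic with p = 0, so cohort sweeps stay total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise SampleSizeError(
            f"each group needs n >= 2, got {len(x)} and {len(y)}"
        )
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return StatResult(statistic=0.0, p_value=1.0, df=float("nan"),
                              n=(len(x), len(y)))
        sign = 1.0 if np.mean(x) > np.mean(y) else -1.0
        return StatResult(statistic=sign * float("inf"), p_value=0.0,
                          df=float("nan"), n=(len(x), len(y)))
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df), n=(len(x), len(y)))


def fisher_exact(a: int, b: int, c: int, d: int) -> StatResult:
    """Fisher's exact test on the 2x2 table ((a, b), (c, d)), two-sided.

    Two-sided p sums the hypergeometric probabilities of every table
    with the same margins whose probability does not exceed the
    observed table's.
    """
    counts = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in counts):
        raise PointRangeError(f"cell counts must be non-negative integers, got {counts}")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = sps.contingency.odds_ratio([[a, b], [c, d]], kind="sample").statistic
    return StatResult(statistic=float(odds), p_value=float(p),
                      n=(int(a + b), int(c + d)))


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa, ``(p_o - p_e) / (1 - p_e)``, between two raters.

    Perfect agreement with a degenerate marginal (``p_e = 1``) is
    defined as kappa = 1 rather than 0/0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise SchemaError(f"label vectors differ in shape: {a.shape} vs {b.shape}")
    if len(a) < 1:
        raise SampleSizeError("kappa needs at least one rating pair")
    # p_e = 1 only when both raters use a single (identical) label
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return 1.0
    return float(cohen_kappa_score(a, b))


KAPPA_BANDS = (
    (0.8, "almost perfect"),
    (0.6, "substantial"),
    (0.4, "moderate"),
    (0.2, "fair"),
)


def kappa_band(kappa: float) -> str:
    """Conventional agreement label for a kappa value.

    Band boundaries are half-open upward (0.8 -> "almost perfect",
    0.6 -> "substantial", ...); below 0.2 the label is "slight or poor".
    """
    if kappa > 1.0:
        raise PointRangeError(f"kappa cannot exceed 1, got {kappa}")
    for lo, label in KAPPA_BANDS:
        if kappa >= lo:
            return label
    return "slight or poor"
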