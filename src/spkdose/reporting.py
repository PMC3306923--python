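"""Grouped descriptive statistics and comparisons against external doses.

Produces the study-style summary table — n, mean (sample SD), median, 95% CI
and min-max of the daily dose per scheme, overall and stratified by season
and by community — plus the paired *t*-test of each scheme against
externally supplied per-subject doses (e.g. from a full PBPK model) and a
one-way ANOVA across schemes.

All statistics are computed at full precision on the non-missing values of
each group; the 2-decimal rounding of the printed tables is applied only at
presentation (:func:`round_for_display`).  Confidence intervals use the
Student-t multiplier, mean ± t_{0.975, n-1} · sd / √n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryRow",
    "ComparisonResult",
    "summarize",
    "summary_table",
    "round_for_display",
    "paired_compare",
    "anova_across_schemes",
    "load_study_doses",
]

SCHEME_COLUMNS = ("spk1", "spk2", "spk3")


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics of one group x scheme cell (µg/kg/day)."""

    group: str
    scheme: str
    n: int
    mean: float
    sd: float
    median: float
    ci_low: float
    ci_high: float
    min: float
    max: float


@dataclass(frozen=True)
class ComparisonResult:
    """A significance test outcome, kept for logging as much as inference."""

    test: str  # 'paired_t' or 'one_way_anova'
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    n: int
    note: str = ""


def summarize(values, group: str = "overall", scheme: str = "") -> SummaryRow:
    """Descriptive statistics of one dose list; missing entries dropped.

    An empty group yields n = 0 with NaN statistics.  A single-element group
    has sd = 0 and an undefined (NaN) confidence interval.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = x.size
    if n == 0:
        nan = float("nan")
        return SummaryRow(group, scheme, 0, nan, nan, nan, nan, nan, nan, nan)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    median = float(np.median(x))  # average-of-middle-two for even n
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci_low, ci_high = mean - half, mean + half
    else:
        ci_low = ci_high = float("nan")
    return SummaryRow(
        group, scheme, n, mean, sd, median, ci_low, ci_high, float(x.min()), float(x.max())
    )


def summary_table(doses: pd.DataFrame, schemes=SCHEME_COLUMNS) -> pd.DataFrame:
    """Study-style summary blocks: overall, per season, per community.

    ``doses`` is one row per subject-period with dose columns named by
    ``schemes`` and (optionally) ``season`` and ``community`` columns for
    the stratified blocks.
    """
    blocks: list[tuple[str, pd.DataFrame]] = [("overall", doses)]
    for col, prefix in (("season", ""), ("community", "")):
        if col in doses.columns:
            for value in pd.unique(doses[col].dropna()):
                blocks.append((str(value), doses[doses[col] == value]))
    rows = [
        summarize(sub[scheme], group=name, scheme=scheme)
        for name, sub in blocks
        for scheme in schemes
        if scheme in sub.columns
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def round_for_display(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation rounding of the numeric statistics columns."""
    out = table.copy()
    for col in ("mean", "sd", "median", "ci_low", "ci_high", "min", "max"):
        if col in out.columns:
            out[col] = out[col].round(decimals)
    return out


def paired_compare(spk, reference) -> ComparisonResult:
    """Two-sided paired t-test of scheme doses against matched references.

    Pairs must be aligned (same subject-period order); pairs with either
    side missing are dropped.  With all differences zero the statistic is 0
    and p = 1 by convention (logged); with < 2 complete pairs the test is
    not defined.
    """
    a = np.asarray(pd.Series(spk), dtype=float)
    b = np.asarray(pd.Series(reference), dtype=float)
    if a.shape != b.shape:
        raise InsufficientDataError("paired test needs equal-length aligned columns")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs >= 2 complete pairs, got {n}")
    diffs = a - b
    note = ""
    if np.all(diffs == diffs[0]) and diffs[0] == 0.0:
        statistic, p = 0.0, 1.0
        note = "zero differences; p = 1 by convention"
        logger.warning("paired_compare: %s", note)
    elif np.std(diffs, ddof=1) == 0.0:
        statistic = math.copysign(math.inf, float(diffs[0]))
        p = 0.0
        note = "constant nonzero differences; statistic unbounded"
        logger.warning("paired_compare: %s", note)
    else:
        res = stats.ttest_rel(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    result = ComparisonResult("paired_t", statistic, float(n - 1), p, n, note)
    logger.info("paired t-test: t = %.4g, df = %d, p = %.4g (n = %d)", statistic, n - 1, p, n)
    return result


def anova_across_schemes(*groups) -> ComparisonResult:
    """One-way fixed-effects ANOVA across dose groups (missing dropped).

    Requires at least two groups with at least two values each.  Zero
    between-group variance yields F = 0, p = 1; zero within-group variance
    with distinct means is flagged and reported as an unbounded F with p = 0.
    """
    cleaned = [np.asarray(pd.Series(g).dropna(), dtype=float) for g in groups]
    cleaned = [g for g in cleaned if g.size > 0]
    if len(cleaned) < 2 or sum(g.size >= 2 for g in cleaned) < 2:
        raise InsufficientDataError("one-way ANOVA needs >= 2 groups with >= 2 values")
    grand = np.concatenate(cleaned)
    ss_between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in cleaned)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in cleaned)
    df1 = len(cleaned) - 1
    df2 = grand.size - len(cleaned)
    note = ""
    if ss_within == 0.0:
        if ss_between == 0.0:
            statistic, p = 0.0, 1.0
            note = "all groups identical; F = 0"
        else:
            statistic, p = math.inf, 0.0
            note = "zero within-group variance; F unbounded"
        logger.warning("anova_across_schemes: %s", note)
    else:
        res = stats.f_oneway(*cleaned)
        statistic, p = float(res.statistic), float(res.pvalue)
    result = ComparisonResult("one_way_anova", statistic, (float(df1), float(df2)), p,
                              int(grand.size), note)
    logger.info(
        "one-way ANOVA: F = %.4g, df = (%d, %d), p = %.4g", statistic, df1, df2, result.p_value
    )
    return result


def load_study_doses() -> pd.DataFrame:
    """Packaged per-subject dose table: PBPK and SPK I/II/III doses.

    Columns: subject_id, community (agricultural/urban), season
    (summer/fall), body_wt_kg, pbpk, spk1, spk2, spk3 (µg/kg/day; NaN where
    the printed table shows n.a. for missing spot urine samples).
    """
    path = resources.files("spkdose.data").joinpath("study_doses.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, na_values=["n.a."])
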