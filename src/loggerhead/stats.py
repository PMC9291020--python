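"""Summary statistics for the simulated assemblage and the capture survey.

Covers the correlation tests (annual abundance vs. female proportion;
male:female ratio vs. female abundance), the chi-square comparison of
observed age structure against the base-model expectation, descriptive
summaries (median / quartiles / range per age group), and the survey-block
trend tests on the empirical female proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .growth import GROUP_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "ChiSquareResult",
    "SURVEY_BLOCKS",
    "block_for_year",
    "correlate",
    "chi_square_contingency",
    "age_structure_chi_square",
    "run_summary",
    "female_proportion_by_block",
    "block_trend_tests",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str     # 'pearson' or 'spearman'
    r: float
    n: int
    p_value: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


#: Six chronological survey blocks partitioning 2000-2019; the 2004-2007 and
#: 2016-2017 blocks are Charleston shipping-channel surveys.
SURVEY_BLOCKS = (
    ("2000-2003", range(2000, 2004), False),
    ("2004-2007", range(2004, 2008), True),
    ("2008-2011", range(2008, 2012), False),
    ("2012-2015", range(2012, 2016), False),
    ("2016-2017", range(2016, 2018), True),
    ("2018-2019", range(2018, 2020), False),
)


def block_for_year(year: int) -> tuple[str, int]:
    """(block label, 1-based chronological order) for a survey year."""
    for order, (label, years, _channel) in enumerate(SURVEY_BLOCKS, start=1):
        if year in years:
            return label, order
    raise ValueError(f"year {year} outside the 2000-2019 survey span")


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman uses midranks for ties; p-values come from the t approximation
    on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r), len(x), float(p))


def chi_square_contingency(observed) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the row/column margins; no continuity
    correction (df = (r-1)(c-1) > 1 in all uses here).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.ndim != 2 or min(observed.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(observed < 0):
        raise ValueError("negative counts")
    if np.any(observed.sum(axis=0) == 0) or np.any(observed.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(observed, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def age_structure_chi_square(observed_by_curve: pd.DataFrame,
                             expected_shares) -> ChiSquareResult:
    """Observed age structure (one column per growth-curve variant) against
    the base-model expectation.

    The expected column is the base model's age-group shares scaled to the
    mean observed column total, appended as a fourth column; with three age
    groups and four columns, df = 6.
    """
    obs = observed_by_curve.reindex(list(GROUP_LABELS)).to_numpy(dtype=float)
    shares = np.asarray(expected_shares, dtype=float)
    shares = shares / shares.sum()
    expected = shares * obs.sum(axis=0).mean()
    return chi_square_contingency(np.column_stack([obs, expected]))


def run_summary(summary: pd.DataFrame,
                value: str = "proportion_female") -> pd.DataFrame:
    """Median, quartiles (linear interpolation), min and max of an annual
    quantity per age group over the reported years."""
    rows = []
    for group, sub in summary.groupby("group"):
        v = sub[value].dropna().to_numpy()
        if len(v) == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": group, "median": med, "q1": q1, "q3": q3,
                     "min": v.min(), "max": v.max(), "n_years": len(v)})
    return pd.DataFrame(rows).set_index("group")


def female_proportion_by_block(assignments: pd.DataFrame) -> pd.DataFrame:
    """Observed female proportion per (age group, survey block, growth code).

    ``assignments`` carries ``year``, ``sex``, ``age_group`` and a
    ``growth_code`` column (0 = -5 %, 1 = reconstructed, 2 = +5 %).
    Undetermined animals are excluded from the proportion.
    """
    df = assignments[assignments["sex"].isin(["F", "M"])].copy()
    blocks = df["year"].map(block_for_year)
    df["block"] = blocks.str[0]
    df["block_order"] = blocks.str[1]
    if "growth_code" not in df.columns:
        df["growth_code"] = 1
    grouped = df.groupby(["age_group", "block", "block_order", "growth_code"])
    out = grouped["sex"].agg(
        n="size", females=lambda s: int((s == "F").sum())).reset_index()
    out["proportion_female"] = out["females"] / out["n"]
    return out


def block_trend_tests(proportions: pd.DataFrame) -> pd.DataFrame:
    """Trend tests on the observed female proportion, per age group.

    For each age group: Pearson correlation with the sample size behind
    each proportion; Spearman with the ordinal growth-equation code; and
    Spearman with the chronological block order.  Groups with fewer than
    three blocks of data are skipped with a log notice.

    Returns a tidy frame (test, group, method, r, n, p_value).
    """
    rows = []
    tests = (("sample_size", "n", "pearson"),
             ("growth_equation", "growth_code", "spearman"),
             ("survey_block", "block_order", "spearman"))
    for group, sub in proportions.groupby("age_group"):
        if sub["block_order"].nunique() < 3:
            logger.info("age group %s: <3 survey blocks with data, skipped", group)
            continue
        for test, column, method in tests:
            try:
                res = correlate(sub["proportion_female"], sub[column], method)
            except ValueError:
                logger.info("age group %s: %s test undefined (constant input)",
                            group, test)
                continue
            rows.append({"test": test, "group": group, "method": method,
                         "r": res.r, "n": res.n, "p_value": res.p_value})
    return pd.DataFrame(rows, columns=["test", "group", "method", "r", "n",
                                       "p_value"])
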