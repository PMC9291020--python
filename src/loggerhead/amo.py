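"""Climate-index driver: parse, seasonally average, normalize, and map to
neritic-recruitment ages.

The Atlantic Multidecadal Oscillation (AMO) index arrives as monthly
sea-surface-temperature anomalies in the NOAA ESRL "standard, long" text
format (one row per year: the year followed by twelve monthly values, with a
sentinel such as ``-99.99`` marking months not yet observed).  The driver
pipeline is:

1. parse the monthly series,
2. average April-November of each year (the nesting and hatching season),
3. normalize the annual means to z-scores over a reference span,
4. sum z over each cohort's first eight years of life (ages 0-7), and
5. rank those window sums into quintiles that set the cohort's neritic
   recruitment age NR in {8, ..., 12} (coolest fifth recruits youngest).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NOAA_SENTINEL",
    "SEASON_MONTHS",
    "RecruitmentSchedule",
    "parse_noaa_long",
    "write_noaa_long",
    "seasonal_annual_mean",
    "normalize",
    "cohort_window_sums",
    "assign_recruitment",
]

NOAA_SENTINEL = -99.99

#: April through November — the nesting and hatching season.
SEASON_MONTHS = tuple(range(4, 12))

#: Recruitment ages attached to ascending quintiles of the cohort window sum.
QUINTILE_NR = (8, 9, 10, 11, 12)


class ClimateParseError(ValueError):
    """A malformed row in a NOAA long-format index file."""


def parse_noaa_long(source, sentinel: float = NOAA_SENTINEL) -> pd.DataFrame:
    """Parse a NOAA ESRL long-format monthly index file.

    Parameters
    ----------
    source : str, path-like or file-like
        The file to read.  Each data row is a year followed by twelve
        monthly values; months equal to ``sentinel`` are omitted from the
        output.  Rows whose first token is not an integer year (header or
        trailer lines) are skipped.
    sentinel : float
        Missing-value marker, default -99.99.

    Returns
    -------
    pandas.DataFrame
        Columns ``year``, ``month`` (1-12), ``value``; one row per
        observed month.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    records: list[tuple[int, int, float]] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            year = int(tokens[0])
        except ValueError:
            # Trailer line (e.g. the missing-value note).
            continue
        if len(tokens) == 2:
            # ESRL span header ("first_year last_year").
            continue
        if len(tokens) != 13:
            raise ClimateParseError(
                f"line {lineno}: expected year + 12 monthly values, "
                f"got {len(tokens)} tokens"
            )
        try:
            values = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise ClimateParseError(f"line {lineno}: non-numeric value ({exc})")
        for month, value in enumerate(values, start=1):
            if value == sentinel:
                continue
            records.append((year, month, value))

    frame = pd.DataFrame(records, columns=["year", "month", "value"])
    if frame.duplicated(["year", "month"]).any():
        raise ClimateParseError("duplicate (year, month) entries in input")
    return frame


def write_noaa_long(series: pd.DataFrame, path, sentinel: float = NOAA_SENTINEL) -> None:
    """Write a monthly series back to NOAA long format (round-trip safe)."""
    wide = series.pivot(index="year", columns="month", values="value")
    wide = wide.reindex(columns=range(1, 13)).fillna(sentinel)
    with open(path, "w", encoding="utf-8") as fh:
        for year, row in wide.iterrows():
            vals = "  ".join(f"{v:8.4f}" for v in row.to_numpy())
            fh.write(f"{int(year)}  {vals}\n")


def seasonal_annual_mean(series: pd.DataFrame) -> pd.Series:
    """Mean of the April-November monthly values, per year.

    Years missing any of the eight season months are dropped rather than
    imputed.  Raises ``ValueError`` on an empty series.
    """
    if len(series) == 0:
        raise ValueError("empty monthly series")
    season = series[series["month"].isin(SEASON_MONTHS)]
    by_year = season.groupby("year")["value"]
    complete = by_year.count() == len(SEASON_MONTHS)
    annual = by_year.mean()[complete]
    annual.name = "value"
    return annual


def normalize(annual: pd.Series, reference_span: tuple[int, int]) -> pd.Series:
    """Z-score an annual index against a reference span's grand statistics.

    The grand mean and grand standard deviation (sample convention, n-1)
    are computed from the years inside ``reference_span`` (inclusive); all
    years present are then transformed.  The result carries ``grand_mean``,
    ``grand_sd`` and ``reference_span`` in ``.attrs``.
    """
    first, last = reference_span
    ref = annual[(annual.index >= first) & (annual.index <= last)]
    if len(ref) < 2:
        raise ValueError(
            f"reference span {first}-{last} covers {len(ref)} year(s); need >= 2"
        )
    grand_mean = float(ref.mean())
    grand_sd = float(ref.std(ddof=1))
    if grand_sd == 0.0:
        raise ValueError("constant series inside reference span: grand SD is zero")
    z = (annual - grand_mean) / grand_sd
    z.name = "z"
    z.attrs["grand_mean"] = grand_mean
    z.attrs["grand_sd"] = grand_sd
    z.attrs["reference_span"] = (first, last)
    return z


def cohort_window_sums(z: pd.Series, window: int = 8) -> pd.Series:
    """Sum of z over each cohort's oceanic ages 0 through ``window - 1``.

    The sum for cohort year ``c`` covers calendar years ``c .. c+window-1``
    and is emitted only when all ``window`` annual values exist.
    """
    z = z.sort_index()
    sums: dict[int, float] = {}
    index = set(z.index)
    for cohort_year in z.index:
        years = range(cohort_year, cohort_year + window)
        if all(y in index for y in years):
            sums[cohort_year] = float(z.loc[list(years)].sum())
    out = pd.Series(sums, name="window_sum", dtype=float)
    out.index.name = "cohort_year"
    return out


@dataclass(frozen=True)
class RecruitmentSchedule:
    """Cohort year -> neritic recruitment age NR, with a default for cohorts
    outside the driver's coverage (burn-in years and truncated windows)."""

    nr_by_cohort: dict[int, int] = field(default_factory=dict)
    default_nr: int = 10

    def __post_init__(self) -> None:
        # Quintile-derived schedules only contain 8-12; toy projections may
        # use other recruitment ages, so the type just bounds them to 1-77.
        bad = {y: nr for y, nr in self.nr_by_cohort.items()
               if not 1 <= nr <= 77}
        if bad:
            raise ValueError(f"NR outside 1-77: {bad}")
        if not 1 <= self.default_nr <= 77:
            raise ValueError(f"default NR {self.default_nr} outside 1-77")

    def __getitem__(self, cohort_year: int) -> int:
        return self.nr_by_cohort.get(cohort_year, self.default_nr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.nr_by_cohort.items()), columns=["cohort_year", "nr"]
        )


def assign_recruitment(sums: pd.Series, default_nr: int = 10) -> RecruitmentSchedule:
    """Map window sums to recruitment ages by ascending rank quintiles.

    The five stated percentile bands are exact 20-percentile bands, so the
    sums are ranked ascending (ties broken by earlier cohort year) and cut
    into five contiguous groups whose sizes differ by at most one; the
    lowest fifth gets NR = 8 (cool phase, short oceanic stage) up to the
    highest fifth at NR = 12.  With fewer than five sums every cohort falls
    back to ``default_nr``.
    """
    if len(sums) < 5:
        return RecruitmentSchedule({}, default_nr)
    order = sorted(sums.index, key=lambda y: (sums.loc[y], y))
    bins = np.array_split(np.asarray(order), 5)
    nr_by_cohort = {
        int(year): QUINTILE_NR[i] for i, group in enumerate(bins) for year in group
    }
    return RecruitmentSchedule(nr_by_cohort, default_nr)
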