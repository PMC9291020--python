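"""Stage-structured cohort projection of a theoretical neritic loggerhead
sea turtle assemblage.

Each annual cohort enters the ocean as ``H`` hatchlings per sex, survives
its first year at rate ``A0S``, then at the annual oceanic rate ``OS`` until
its neritic recruitment age ``NR`` (the first neritic rate ``NS`` applies in
the year of recruitment itself), and finally at ``NS`` through a maximum age
of 77.  Projection is fully deterministic: survivorship proportions are
accumulated in double precision and converted to an integer count by a
single floor per (cohort, age, sex) cell.

Model variants
--------------
M1  fixed hatchling abundance, fixed 0.85 female split, fixed NR = 10
M2  fixed abundance and split, climate-driven NR
M3  climate-driven NR with +/-5 % female-proportion swing
M4  climate-driven NR with +/-10 % swing
M5  as M4 plus a 15-year sinusoid in annual nest counts
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amo import RecruitmentSchedule

__all__ = [
    "StageSurvival",
    "HatchlingProduction",
    "SexSplitRule",
    "ModelConfig",
    "hatchlings_fixed",
    "hatchlings_sinusoid",
    "sex_split",
    "survivorship_proportion",
    "survivorship_curve",
    "neritic_total_closed_form",
    "project",
    "age_group_summary",
    "mf_ratio_series",
    "whole_percent_shares",
    "AGE_GROUPS",
]

VARIANTS = ("M1", "M2", "M3", "M4", "M5")

#: (label, min age, max age); the lower bound of the first group is in
#: practice each cohort's own NR since pre-NR ages are oceanic.
AGE_GROUPS = (("NR-19", 0, 19), ("20-29", 20, 29), ("30-77", 30, 77))


@dataclass(frozen=True)
class StageSurvival:
    """Fixed annual survival rates for the three post-hatchling stages."""

    a0s: float = 0.4    # age-0 survival: ocean entry to suitable habitat
    os: float = 0.713   # annual oceanic-stage survival
    ns: float = 0.854   # annual neritic-stage survival

    def __post_init__(self) -> None:
        for name in ("a0s", "os", "ns"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0, 1)")


@dataclass(frozen=True)
class HatchlingProduction:
    """Nest counts and the nest -> ocean-entering hatchling conversion."""

    eggs_per_nest: int = 115
    ocean_entry_fraction: float = 0.5
    fixed_nests: int = 45_000          # mean of the reported 30k-60k range
    sin_amplitude: float = 15_000.0
    sin_offset: float = 45_000.0
    sin_phase_divisor: float = 2.5

    def __post_init__(self) -> None:
        if self.eggs_per_nest <= 0:
            raise ValueError("eggs_per_nest must be positive")
        if not 0.0 < self.ocean_entry_fraction <= 1.0:
            raise ValueError("ocean_entry_fraction must lie in (0, 1]")


def hatchlings_fixed(production: HatchlingProduction, nests: int | None = None) -> int:
    """Ocean-entering hatchlings from a fixed nest count (floored)."""
    n = production.fixed_nests if nests is None else nests
    return math.floor(n * production.eggs_per_nest * production.ocean_entry_fraction)


def hatchlings_sinusoid(order: int, production: HatchlingProduction) -> tuple[int, int]:
    """Nests and hatchlings for sinusoid order ``o`` (1-based).

    ``nests = floor(sin(o / 2.5) * 15,000 + 45,000)`` with the argument in
    radians, giving the 15-year smooth oscillation in annual nest counts;
    hatchlings follow the fixed-production conversion.
    """
    if order < 1:
        raise ValueError("order is 1-based")
    nests = math.floor(
        math.sin(order / production.sin_phase_divisor) * production.sin_amplitude
        + production.sin_offset
    )
    return nests, hatchlings_fixed(production, nests)


# Female hatchling counts by recruitment age.  Each entry equals
# floor(female proportion x 2,587,500); the +/-5 % table spans proportions
# 0.80-0.90 and the +/-10 % table 0.75-0.95, lower proportions in the cool
# phase (low NR).
FEMALES_BY_NR_5PCT = {8: 2_070_000, 9: 2_134_687, 10: 2_199_375,
                      11: 2_264_062, 12: 2_328_750}
FEMALES_BY_NR_10PCT = {8: 1_940_625, 9: 2_070_000, 10: 2_199_375,
                       11: 2_328_750, 12: 2_458_125}
FEMALE_FRACTION_BY_NR = {8: 0.75, 9: 0.80, 10: 0.85, 11: 0.90, 12: 0.95}

FIXED_FEMALES = 2_199_375   # 0.85 of the fixed total
FIXED_MALES = 388_125


@dataclass(frozen=True)
class SexSplitRule:
    """How a cohort's hatchlings divide into females and males.

    M1/M2 use the fixed 0.85/0.15 split; M3/M4 take the female count from a
    printed lookup by NR (male = total - female); M5 applies the M4 female
    *fraction* to its variable total.
    """

    variant: str = "M1"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def split(self, total_hatchlings: int, nr: int) -> tuple[int, int]:
        return sex_split(total_hatchlings, nr, self)


def sex_split(total_hatchlings: int, nr: int, rule: SexSplitRule) -> tuple[int, int]:
    """(females, males) entering the ocean for one cohort."""
    if total_hatchlings < 0:
        raise ValueError("negative hatchling total")
    v = rule.variant
    if v in ("M1", "M2"):
        return FIXED_FEMALES, FIXED_MALES
    if v in ("M3", "M4"):
        table = FEMALES_BY_NR_5PCT if v == "M3" else FEMALES_BY_NR_10PCT
        try:
            females = table[nr]
        except KeyError:
            raise ValueError(f"no female lookup for NR={nr} under {v}")
        return females, total_hatchlings - females
    # M5: proportional split on a variable total
    try:
        fraction = FEMALE_FRACTION_BY_NR[nr]
    except KeyError:
        raise ValueError(f"no female fraction for NR={nr} under M5")
    females = math.floor(fraction * total_hatchlings)
    return females, total_hatchlings - females


def survivorship_proportion(age: int, nr: int, survival: StageSurvival) -> float:
    """Proportion of ocean-entering hatchlings alive at ``age``.

    Recurrence: p(0) = A0S; p(a) = p(a-1) x OS for 1 <= a <= NR-1;
    p(a) = p(a-1) x NS for a >= NR (first NS applied in the year of NR).
    """
    if not 0 <= age <= 77:
        raise ValueError(f"age {age} outside 0-77")
    if age == 0:
        return survival.a0s
    n_os = min(age, nr - 1)
    n_ns = age - n_os
    return survival.a0s * survival.os ** n_os * survival.ns ** n_ns


def survivorship_curve(nr: int, survival: StageSurvival, max_age: int = 77) -> np.ndarray:
    """p(0) .. p(max_age) as an array, by the same recurrence."""
    rates = np.where(np.arange(1, max_age + 1) <= nr - 1, survival.os, survival.ns)
    return survival.a0s * np.concatenate([[1.0], np.cumprod(rates)])


def neritic_total_closed_form(h: float, nr: int, survival: StageSurvival,
                              max_age: int = 77) -> float:
    """Pre-floor neritic total for one sex at equilibrium, via the geometric
    series: H x A0S x OS^(NR-1) x sum_{k=1}^{max_age+1-NR} NS^k."""
    k = np.arange(1, max_age + 2 - nr)
    return h * survival.a0s * survival.os ** (nr - 1) * float(np.sum(survival.ns ** k))


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed for one projection run.

    The first ``burn_in`` cohorts only populate the age structure; reported
    calendar years are ``start_year .. start_year + reported_span - 1``.
    Burn-in cohorts use the schedule's default NR and, under M5, the fixed
    mean production.
    """

    variant: str = "M1"
    survival: StageSurvival = field(default_factory=StageSurvival)
    production: HatchlingProduction = field(default_factory=HatchlingProduction)
    schedule: RecruitmentSchedule = field(default_factory=RecruitmentSchedule)
    start_year: int = 1856
    reported_span: int = 165
    burn_in: int = 77
    max_age: int = 77

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.burn_in < self.max_age:
            raise ValueError("burn-in must cover the maximum age")

    @property
    def n_cohorts(self) -> int:
        return self.burn_in + self.reported_span

    @property
    def split(self) -> SexSplitRule:
        return SexSplitRule(self.variant)

    @property
    def reported_years(self) -> range:
        return range(self.start_year, self.start_year + self.reported_span)


def _cohort_inputs(config: ModelConfig):
    """Yield (cohort_year, nr, h_female, h_male) for all cohorts."""
    first_cohort = config.start_year - config.burn_in
    fixed_total = hatchlings_fixed(config.production)
    for cohort_year in range(first_cohort, config.start_year + config.reported_span):
        burn_in = cohort_year < config.start_year
        if config.variant == "M1" or burn_in:
            nr = config.schedule.default_nr
        else:
            nr = config.schedule[cohort_year]
        if config.variant == "M5" and not burn_in:
            order = cohort_year - config.start_year + 1
            _, total = hatchlings_sinusoid(order, config.production)
        else:
            total = fixed_total
        h_female, h_male = sex_split(total, nr, config.split)
        yield cohort_year, nr, h_female, h_male


def project(config: ModelConfig) -> pd.DataFrame:
    """Project all cohorts and return the assemblage as a tidy table.

    Columns: ``cohort_year, year, age, nr, sex, realm, count``; one row per
    (cohort, age, sex) cell with ``year = cohort_year + age`` and
    ``realm = 'neritic'`` iff ``age >= nr``.  Counts are
    ``floor(h_sex x p(age))``.
    """
    ages = np.arange(config.max_age + 1)
    frames = []
    for cohort_year, nr, h_female, h_male in _cohort_inputs(config):
        p = survivorship_curve(nr, config.survival, config.max_age)
        realm = np.where(ages >= nr, "neritic", "oceanic")
        for sex, h in (("F", h_female), ("M", h_male)):
            frames.append(pd.DataFrame({
                "cohort_year": cohort_year,
                "year": cohort_year + ages,
                "age": ages,
                "nr": nr,
                "sex": sex,
                "realm": realm,
                "count": np.floor(h * p).astype(np.int64),
            }))
    table = pd.concat(frames, ignore_index=True)
    table.attrs["variant"] = config.variant
    table.attrs["reported_years"] = (config.start_year,
                                     config.start_year + config.reported_span - 1)
    return table


def _group_label(age: np.ndarray) -> np.ndarray:
    return np.select([age <= 19, age <= 29], ["NR-19", "20-29"], default="30-77")


def age_group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per reported year and age group: neritic counts by sex and derived
    ratios.

    Columns: ``year, group, females, males, total, proportion_female,
    mf_ratio``.  The first group runs from each cohort's own NR through age
    19.  Years with no neritic animals in a group yield missing proportions.
    """
    first, last = table.attrs.get("reported_years", (table["year"].min(),
                                                     table["year"].max()))
    neritic = table[(table["realm"] == "neritic")
                    & (table["year"] >= first) & (table["year"] <= last)].copy()
    neritic["group"] = _group_label(neritic["age"].to_numpy())
    counts = (neritic.pivot_table(index=["year", "group"], columns="sex",
                                  values="count", aggfunc="sum", fill_value=0)
              .reindex(columns=["F", "M"], fill_value=0)
              .reset_index()
              .rename(columns={"F": "females", "M": "males"}))
    counts.columns.name = None
    counts["total"] = counts["females"] + counts["males"]
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["proportion_female"] = np.where(
            counts["total"] > 0, counts["females"] / counts["total"], np.nan)
        counts["mf_ratio"] = np.where(
            counts["females"] > 0, counts["males"] / counts["females"], np.nan)
    return counts


def mf_ratio_series(summary: pd.DataFrame, group: str = "30-77") -> pd.Series:
    """Annual male:female ratio for one age group (missing where no females)."""
    sub = summary[summary["group"] == group].set_index("year")
    return sub["mf_ratio"]


def whole_percent_shares(counts) -> list[int]:
    """Whole-percent shares summing to 100 by largest-remainder rounding.

    Printed percentage breakdowns conventionally sum to 100; flooring each
    share and distributing the leftover points to the largest fractional
    remainders reproduces that convention deterministically.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("shares undefined for a non-positive total")
    raw = 100.0 * counts / total
    floors = np.floor(raw).astype(int)
    remainder = raw - floors
    short = 100 - int(floors.sum())
    for i in np.argsort(-remainder)[:short]:
        floors[i] += 1
    return floors.tolist()
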