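"""Sex assignment from plasma testosterone and age assignment from carapace
length.

Sex is read from circulating testosterone (T, pg/ml) against assay-era
thresholds: below the female ceiling is female, above the male floor is
male, and the closed interval between them is undetermined.  The thresholds
changed when assay reagents changed in 2004 (200/300 -> 400/500 pg/ml); the
2019 ELISA kept the post-2004 reference range.  Large animals
(>= 75.1 cm SCLmin) classified male are flagged for caution because
pubescent females can carry elevated T; the flag never changes the label.

Age comes from a power-law size-at-age curve ``SCL = a x age^b`` with the
reconstructed coefficients a = 18.705 cm and b = 0.4403, evaluated at a
multiplicative scale in {0.95, 1.00, 1.05} to bracket somatic-growth
variability.  Age groups (<= 19, 20-29, 30-77) are delimited by the curve
evaluated at the half-ages 19.5 and 29.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssayEra",
    "ERAS",
    "era_for_year",
    "SexAssignment",
    "assign_sex",
    "classify_captures",
    "GrowthCurve",
    "fit_power_curve",
    "age_group_bounds",
    "classify_age_group",
    "CAUTION_SCL_CM",
    "GROUP_LABELS",
]

CAUTION_SCL_CM = 75.1
GROUP_LABELS = ("NR-19", "20-29", "30-77")

#: Boundary half-ages delimiting the three age groups.
GROUP_BOUNDARY_AGES = (19.5, 29.5)


@dataclass(frozen=True)
class AssayEra:
    """Testosterone thresholds (pg/ml) for one assay era."""

    name: str
    female_max: float   # T below this is female
    male_min: float     # T above this is male

    def __post_init__(self) -> None:
        if not self.female_max < self.male_min:
            raise ValueError("female ceiling must lie below male floor")


ERAS = {
    "RIA_pre2004": AssayEra("RIA_pre2004", 200.0, 300.0),
    "RIA_2004plus": AssayEra("RIA_2004plus", 400.0, 500.0),
    "ELISA_2019": AssayEra("ELISA_2019", 400.0, 500.0),
}


def era_for_year(year: int) -> AssayEra:
    """Assay era in effect for a capture year."""
    if year < 2004:
        return ERAS["RIA_pre2004"]
    if year < 2019:
        return ERAS["RIA_2004plus"]
    return ERAS["ELISA_2019"]


@dataclass(frozen=True)
class SexAssignment:
    sex: str            # 'F', 'M' or 'U'
    caution_flag: bool  # male label on an animal >= 75.1 cm SCLmin


def assign_sex(testosterone: float, era: AssayEra | str,
               scl_min: float | None = None) -> SexAssignment:
    """Classify one animal's sex from its testosterone concentration.

    Boundary values (exactly at a threshold) fall in the undetermined band,
    matching the strict inequalities for F and M and the inclusive range
    for U.
    """
    if isinstance(era, str):
        era = ERAS[era]
    if testosterone < 0:
        raise ValueError(f"negative testosterone {testosterone}")
    if testosterone < era.female_max:
        sex = "F"
    elif testosterone > era.male_min:
        sex = "M"
    else:
        sex = "U"
    caution = sex == "M" and scl_min is not None and scl_min >= CAUTION_SCL_CM
    if caution:
        logger.info(
            "male label on %.1f cm SCLmin animal (T=%.0f pg/ml): cautious "
            "assignment, pubescent females can show elevated T",
            scl_min, testosterone,
        )
    return SexAssignment(sex, caution)


@dataclass(frozen=True)
class GrowthCurve:
    """Power-law size-at-age model ``SCL = scale x a x age^b``."""

    a: float = 18.705       # cm at age 1
    b: float = 0.4403       # allometric exponent
    scale: float = 1.0      # growth-variability bracket: 0.95, 1.00 or 1.05
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if not 0 < self.b < 1:
            raise ValueError("exponent b must lie in (0, 1)")

    def with_scale(self, scale: float) -> "GrowthCurve":
        return replace(self, scale=scale)

    def size_at_age(self, age):
        """Predicted SCLmin (cm) at ``age`` (years, > 0)."""
        age = np.asarray(age, dtype=float)
        if np.any(age <= 0):
            raise ValueError("age must be positive")
        out = self.scale * self.a * age ** self.b
        return float(out) if out.ndim == 0 else out

    def age_at_size(self, size):
        """Inverse of :meth:`size_at_age`."""
        size = np.asarray(size, dtype=float)
        if np.any(size <= 0):
            raise ValueError("size must be positive")
        out = (size / (self.scale * self.a)) ** (1.0 / self.b)
        return float(out) if out.ndim == 0 else out


def fit_power_curve(ages, sizes) -> GrowthCurve:
    """Least-squares fit of ``log(size) = log(a) + b log(age)``.

    Returns the fitted curve at scale 1.0 with the coefficient of
    determination on the log scale.
    """
    ages = np.asarray(ages, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(ages) < 2 or len(ages) != len(sizes):
        raise ValueError("need >= 2 (age, size) pairs of equal length")
    if np.any(ages <= 0) or np.any(sizes <= 0):
        raise ValueError("ages and sizes must be positive")
    x, y = np.log(ages), np.log(sizes)
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return GrowthCurve(a=float(np.exp(log_a)), b=float(b), r_squared=r2)


def age_group_bounds(curve: GrowthCurve) -> tuple[float, float]:
    """Size ceilings (cm SCLmin) of the <=19 and 20-29 groups.

    Evaluated at the half-ages 19.5 and 29.5; unrounded values are used for
    classification and reported at one decimal place.
    """
    c1, c2 = (curve.size_at_age(a) for a in GROUP_BOUNDARY_AGES)
    return c1, c2


def classify_age_group(scl_min: float, curve: GrowthCurve) -> str:
    """Age group from capture size under one growth-curve variant.

    Sizes are measured to 0.1 cm, so the comparison uses the ceilings at
    that same reported precision: an animal exactly at a 1-dp ceiling
    belongs to the lower group.
    """
    c1, c2 = (round(c, 1) for c in age_group_bounds(curve))
    if scl_min <= c1 + 1e-9:
        return GROUP_LABELS[0]
    if scl_min <= c2 + 1e-9:
        return GROUP_LABELS[1]
    return GROUP_LABELS[2]


def classify_captures(records: pd.DataFrame,
                      curve: GrowthCurve | None = None) -> pd.DataFrame:
    """Vectorised sex and age-group assignment for a capture table.

    ``records`` needs columns ``testosterone_pg_ml``, ``scl_min_cm`` and
    either ``era`` (era name) or ``year``.  Returns a copy with ``sex``,
    ``age_group`` and ``caution_flag`` columns appended.
    """
    curve = curve or GrowthCurve()
    out = records.copy()
    if "era" in out.columns:
        eras = out["era"].map(lambda n: ERAS[n])
    else:
        eras = out["year"].map(era_for_year)
    t = out["testosterone_pg_ml"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative testosterone in capture table")
    female_max = np.array([e.female_max for e in eras])
    male_min = np.array([e.male_min for e in eras])
    sex = np.select([t < female_max, t > male_min], ["F", "M"], default="U")
    scl = out["scl_min_cm"].to_numpy(dtype=float)
    out["sex"] = sex
    out["caution_flag"] = (sex == "M") & (scl >= CAUTION_SCL_CM)
    c1, c2 = (round(c, 1) for c in age_group_bounds(curve))
    out["age_group"] = np.select([scl <= c1 + 1e-9, scl <= c2 + 1e-9],
                                 [GROUP_LABELS[0], GROUP_LABELS[1]],
                                 default=GROUP_LABELS[2])
    n_flagged = int(out["caution_flag"].sum())
    if n_flagged:
        logger.info("%d male assignment(s) >= %.1f cm SCLmin flagged for caution",
                    n_flagged, CAUTION_SCL_CM)
    return out
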