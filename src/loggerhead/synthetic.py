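"""Seeded synthetic data: a climate-index driver and trawl-capture records.

The real inputs are the NOAA AMO monthly index (downloadable, not bundled)
and a two-decade trawl-capture table that is not public.  These generators
emulate both with known ground truth so the whole pipeline is testable
offline: the driver as one multidecadal sinusoid plus AR(1) monthly noise,
the captures with per-sex lognormal testosterone and a configured true
female fraction.

A single seed fans out to independent substreams per component, so stages
can be regenerated independently yet reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import era_for_year

__all__ = [
    "SynthAmoConfig",
    "SynthCaptureConfig",
    "synth_amo",
    "synth_captures",
]


@dataclass(frozen=True)
class SynthAmoConfig:
    """One oscillation plus red noise, mimicking the AMO's multidecadal
    signal in the unsmoothed monthly record.

    Defaults: a 65-year period (the index's characteristic periodicity),
    0.2 degC anomaly amplitude, and monthly AR(1) noise (phi = 0.5,
    innovation SD 0.1 degC) for the unsmoothed month-to-month variability.
    """

    start_year: int = 1856
    n_years: int = 165
    period_years: float = 65.0
    amplitude: float = 0.2
    ar1_coefficient: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_years <= 0:
            raise ValueError("period must be positive")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")


def synth_amo(config: SynthAmoConfig) -> pd.DataFrame:
    """Monthly climate-index series (columns year, month, value)."""
    rng = np.random.default_rng([config.seed, 0x0A30])
    n = config.n_years * 12
    t_years = np.arange(n) / 12.0
    signal = config.amplitude * np.sin(2 * math.pi * t_years / config.period_years)
    noise = np.zeros(n)
    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=n)
        phi = config.ar1_coefficient
        # stationary start so early years are not systematically calmer
        noise[0] = eps[0] / math.sqrt(1 - phi ** 2)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]
    years = config.start_year + np.arange(n) // 12
    months = np.arange(n) % 12 + 1
    return pd.DataFrame({"year": years, "month": months,
                         "value": signal + noise})


@dataclass(frozen=True)
class SynthCaptureConfig:
    """Trawl-capture records with known true sex.

    Testosterone is lognormal per sex (strictly positive, right-skewed, as
    hormone concentrations are), anchored well clear of the assay
    thresholds by default: female median 50 pg/ml, male median 2000 pg/ml.
    Sizes are lognormal clipped to the 45-110 cm SCLmin range the trawl
    survey encounters.  ``female_fraction`` may be a constant or a
    (start, end) pair applied linearly over the survey years.
    """

    start_year: int = 2000
    end_year: int = 2019
    n_per_year: int = 116
    female_fraction: float | tuple[float, float] = 0.67
    size_log_mean: float = math.log(68.0)
    size_log_sd: float = 0.14
    size_min_cm: float = 45.0
    size_max_cm: float = 110.0
    t_female_median: float = 50.0
    t_female_log_sd: float = 0.6
    t_male_median: float = 2000.0
    t_male_log_sd: float = 0.5
    seed: int = 0

    def fraction_for_year(self, year: int) -> float:
        if isinstance(self.female_fraction, tuple):
            lo, hi = self.female_fraction
            span = max(self.end_year - self.start_year, 1)
            f = lo + (hi - lo) * (year - self.start_year) / span
        else:
            f = float(self.female_fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"female fraction {f} outside [0, 1]")
        return f


def synth_captures(config: SynthCaptureConfig) -> pd.DataFrame:
    """Capture records with the truth column alongside.

    Columns: ``id, year, survey_block, scl_min_cm, testosterone_pg_ml,
    era, true_sex``.  ``true_sex`` is the generating label; classification
    sees only testosterone and era.
    """
    from .stats import block_for_year

    rng = np.random.default_rng([config.seed, 0xCAB])
    frames = []
    next_id = 1
    for year in range(config.start_year, config.end_year + 1):
        n = config.n_per_year
        f = config.fraction_for_year(year)
        is_female = rng.random(n) < f
        sizes = np.clip(
            rng.lognormal(config.size_log_mean, config.size_log_sd, size=n),
            config.size_min_cm, config.size_max_cm,
        )
        t = np.where(
            is_female,
            rng.lognormal(math.log(config.t_female_median),
                          config.t_female_log_sd, size=n),
            rng.lognormal(math.log(config.t_male_median),
                          config.t_male_log_sd, size=n),
        )
        block, _ = block_for_year(year)
        frames.append(pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "year": year,
            "survey_block": block,
            "scl_min_cm": sizes,
            "testosterone_pg_ml": t,
            "era": era_for_year(year).name,
            "true_sex": np.where(is_female, "F", "M"),
        }))
        next_id += n
    return pd.concat(frames, ignore_index=True)
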