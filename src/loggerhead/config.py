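"""TOML run configuration with validated defaults.

Every default equals the corresponding printed model constant; an empty
config file therefore reproduces the baseline run exactly.  Unknown keys
and out-of-range values are rejected with all offenders listed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field

from .cohort import HatchlingProduction, StageSurvival, VARIANTS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    variant: str = "M1"
    amo_path: str | None = None
    synthetic_amo: bool = False
    captures_path: str | None = None
    out_dir: str = "."
    a0s: float = 0.4
    os: float = 0.713
    ns: float = 0.854
    eggs_per_nest: int = 115
    ocean_entry_fraction: float = 0.5
    fixed_nests: int = 45_000
    growth_scale: float = 1.0
    default_nr: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def survival(self) -> StageSurvival:
        return StageSurvival(self.a0s, self.os, self.ns)

    def production(self) -> HatchlingProduction:
        return HatchlingProduction(
            eggs_per_nest=self.eggs_per_nest,
            ocean_entry_fraction=self.ocean_entry_fraction,
            fixed_nests=self.fixed_nests,
        )

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _validate(values: dict) -> list[str]:
    problems = []
    if values.get("variant") not in VARIANTS:
        problems.append(f"variant must be one of {VARIANTS}")
    for key in ("a0s", "os", "ns"):
        v = values[key]
        if not 0.0 < v < 1.0:
            problems.append(f"{key}={v} outside (0, 1)")
    if not 0.0 < values["ocean_entry_fraction"] <= 1.0:
        problems.append("ocean_entry_fraction outside (0, 1]")
    if values["eggs_per_nest"] <= 0:
        problems.append("eggs_per_nest must be positive")
    if values["growth_scale"] not in (0.95, 1.0, 1.05):
        problems.append("growth_scale must be 0.95, 1.0 or 1.05")
    if values["default_nr"] not in range(8, 13):
        problems.append("default_nr must lie in 8..12")
    return problems


def load_config(path) -> RunConfig:
    """Load a TOML config; omitted keys take the model defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = sorted(set(raw) - set(_FIELDS))
    values = {name: raw.get(name, f.default) for name, f in _FIELDS.items()}
    problems = ([f"unknown key: {k}" for k in unknown]) + _validate(values)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    return RunConfig(**values)


def save_config(config: RunConfig, path) -> None:
    """Write a config back as TOML (round-trips through load_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in _FIELDS:
            v = getattr(config, name)
            if v is None:
                continue
            if isinstance(v, bool):
                fh.write(f"{name} = {'true' if v else 'false'}\n")
            elif isinstance(v, str):
                fh.write(f'{name} = "{v}"\n')
            else:
                fh.write(f"{name} = {v}\n")
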