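"""Scenario parameterizations of the surveillance rules.

A :class:`ScenarioConfig` bundles every threshold and lookback the rules
engine consults.  Three named presets ship as YAML files:

``sep2_based``
    All parameters enabled, closest to the CMS severe-sepsis definition.
``near_sep2``
    Identical except the SBP decrease >40 mm Hg parameter is disabled.
``conservative``
    Additionally requires a creatinine rise >=0.5 mg/dL alongside the
    2.0 mg/dL threshold, caps qualifying bilirubin at 10 mg/dL, and
    disables the hematologic parameters (platelets, INR).

Each successive preset only restricts criteria, so the flagged sets nest:
conservative ⊆ near_sep2 ⊆ sep2_based on any cohort.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ScenarioConfig", "PRESET_NAMES", "preset", "load_scenario"]

PRESET_NAMES = ("sep2_based", "near_sep2", "conservative")


@dataclass(frozen=True)
class ScenarioConfig:
    """All thresholds, switches and lookbacks of one surveillance scenario."""

    name: str
    # organ-dysfunction parameters
    sbp_drop_enabled: bool = True
    sbp_drop_mmHg: float = 40.0       # drop from baseline must exceed this (strict)
    sbp_low_mmHg: float = 90.0        # SBP strictly below
    map_low_mmHg: float = 65.0        # MAP strictly below
    lactate_high_mmol_L: float = 2.0  # strictly above
    bilirubin_low_mg_dL: float = 2.0  # inclusive (>=)
    bilirubin_cap_mg_dL: float | None = None  # inclusive upper bound when set
    creatinine_high_mg_dL: float = 2.0        # inclusive (>=)
    creatinine_delta_required: bool = False
    creatinine_delta_mg_dL: float = 0.5       # inclusive rise within lookback
    platelets_inr_enabled: bool = True
    platelets_low_per_uL: float = 100_000.0   # strictly below
    inr_high: float = 1.5                     # strictly above
    # lookbacks (hours)
    lactate_lookback_h: float = 12.0
    creatinine_lookback_h: float = 72.0
    default_lookback_h: float = 30.0
    # SIRS thresholds (all strict inequalities, as stated)
    temp_high_C: float = 38.3
    temp_low_C: float = 36.0
    hr_high_bpm: float = 90.0
    rr_high_bpm: float = 20.0
    wbc_high_per_mm3: float = 12_000.0
    wbc_low_per_mm3: float = 4_000.0
    band_high_pct: float = 10.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def preset(name: str) -> ScenarioConfig:
    """Load one of the immutable shipped presets by name."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    text = resources.files("sepscreen.presets").joinpath(f"{name}.yaml").read_text()
    return ScenarioConfig.from_dict(yaml.safe_load(text))


def load_scenario(source) -> ScenarioConfig:
    """Load a scenario from a preset name or a YAML file path."""
    if isinstance(source, str) and source in PRESET_NAMES:
        return preset(source)
    return ScenarioConfig.from_dict(yaml.safe_load(Path(source).read_text()))
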