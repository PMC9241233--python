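"""YAML pipeline configuration with range-checked, fully defaulted values.

Defaults are the standard operating point of the method: essentiality at
BF >= 10, response genes essential in 1-80% of lines, elastic-net L1 ratio
0.25 with inverse strength 1.0, strong associations at |coeff| > 1.2,
feature support >= 7, dedup at PCC >= 0.9, bootstrap B = 1000 and edge calls
at P <= 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "validate_config"]

_RANGES = {
    "bf_threshold": (-1e6, 1e6),
    "min_frac": (0.0, 1.0),
    "max_frac": (0.0, 1.0),
    "coeff_cut": (0.0, 1e6),
    "min_support": (1, 10**9),
    "dedup_pcc": (0.0, 1.0),
    "l1_ratio": (0.0, 1.0),
    "C": (1e-12, 1e12),
    "B": (1, 10**9),
    "alpha": (1e-12, 1.0),
    "min_abs_dpcc": (0.0, 2.0),
    "emt_hi_cut": (-1e6, 1e6),
    "emt_lo_cut": (-1e6, 1e6),
    "seed": (0, 2**31 - 1),
}


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place."""

    # inputs (paths) or a simulate block
    fitness: str | None = None
    mutations: str | None = None
    expression: str | None = None
    metadata: str | None = None
    simulate: dict | None = None

    # thresholds
    bf_threshold: float = 10.0
    min_frac: float = 0.01
    max_frac: float = 0.80
    coeff_cut: float = 1.2
    min_support: int = 7
    dedup_pcc: float = 0.9
    alpha: float = 0.001
    min_abs_dpcc: float = 0.0
    emt_hi_cut: float = 1.0
    emt_lo_cut: float = -4.0

    # regression
    l1_ratio: float = 0.25
    C: float = 1.0

    # bootstrap
    B: int = 1000
    screen_abs_dpcc: float | None = None
    contexts: list[str] | str = "strong"

    seed: int = 0
    out_dir: str = "contextnet_out"

    def validate(self) -> "PipelineConfig":
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if not (lo <= value <= hi):
                raise ValueError(f"config field {name!r} = {value} outside allowed range [{lo}, {hi}]")
        if self.min_frac > self.max_frac:
            raise ValueError("min_frac must not exceed max_frac")
        if self.emt_lo_cut > self.emt_hi_cut:
            raise ValueError("emt_lo_cut must not exceed emt_hi_cut")
        if self.screen_abs_dpcc is not None and not (0.0 <= self.screen_abs_dpcc <= 2.0):
            raise ValueError("screen_abs_dpcc must lie in [0, 2]")
        return self


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load, default and range-check a YAML config; unknown keys are an error."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a YAML mapping")
            data = loaded
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown config keys {unknown}; valid keys: {sorted(valid)}")
    return PipelineConfig(**data).validate()
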