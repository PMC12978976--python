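"""Pipeline configuration: one YAML file is the single source of thresholds.

Every gap-filling decision (proximity radii, movement-unit limits, quantile
rule, alpha) lives in the config so it is visible and versionable. Unknown
keys raise, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .hand_metrics import MovementUnitParams
from .segmentation import EventThresholds


@dataclass
class PipelineConfig:
    seed: int = 7
    out_dir: str = "feedkin_out"
    motion_dir: str | None = None      # None -> simulate a cohort
    alpha: float = 0.05
    quantile_rule: str = "haverage"
    log_level: str = "INFO"
    thresholds: EventThresholds = field(default_factory=EventThresholds)
    movement_units: MovementUnitParams = field(default_factory=MovementUnitParams)
    filter_cutoff_hz: float = 6.0
    simulate: dict = field(default_factory=dict)   # SimConfig / CohortSpec overrides

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


_SECTION_TYPES = {
    "segmentation": ("thresholds", EventThresholds),
    "hand_metrics": ("movement_units", MovementUnitParams),
}

_HAND_METRIC_ALIASES = {
    "amplitude_limit_mps": "amplitude_limit",
    "min_peak_interval_s": "min_peak_interval",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline YAML config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    kwargs: dict = {}
    top_fields = {f.name for f in fields(PipelineConfig)}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            attr, cls = _SECTION_TYPES[key]
            value = dict(value or {})
            if key == "hand_metrics":
                cutoff = value.pop("filter_cutoff_hz", None)
                if cutoff is not None:
                    kwargs["filter_cutoff_hz"] = float(cutoff)
                value = {_HAND_METRIC_ALIASES.get(k, k): v for k, v in value.items()}
            allowed = {f.name for f in fields(cls)}
            bad = set(value) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in [{key}]: {sorted(bad)}")
            kwargs[attr] = cls(**value)
        elif key in top_fields:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    return PipelineConfig(**kwargs)
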