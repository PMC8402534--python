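"""Pipeline configuration with the published constants as defaults.

All tunable thresholds live here so a single YAML file (plus CLI overrides)
reproduces or varies a run: the four somatic-filter thresholds, the FSP
tailoring IC50 threshold, the non-binder rank penalty threshold (1000 nM),
the fixed funnel-comparator thresholds (IC50 500 nM, TPM 0.50), the
expressed-gene TPM floor of the weighting factor, and the epitope length.
Serialization round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import SchemaError
from .variants import FilterConfig


@dataclass(frozen=True)
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    tailoring_threshold_nm: float = 1000.0
    penalty_threshold_nm: float = 1000.0
    funnel_ic50_nm: float = 500.0
    funnel_tpm_min: float = 0.50
    tpm_floor: float = 0.50
    epitope_length: int = 9
    tie_break: str = "ic50_then_id"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
        if "filters" in data and isinstance(data["filters"], dict):
            data["filters"] = FilterConfig(**data["filters"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)
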