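"""Pipeline configuration: nested dataclasses with strict YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .association import ScreenConfig
from .variant_filter import FilterConfig


@dataclass
class CNVConfig:
    penalty: float = 2.0
    gain_threshold: float = 0.7
    loss_threshold: float = -0.7
    gene_exon_fraction: float = 0.75
    n_gc_strata: int = 10


@dataclass
class DoseResponseConfig:
    mode: str = "per_experiment"   # per_experiment | pooled
    control: float = 1.0


@dataclass
class SimulateConfig:
    n_samples: int = 161
    artifact_rate: float = 0.1
    n_lines: int = 8
    cv_noise: float = 0.05
    n_coverage_bins: int = 2000
    coverage_depth: float = 100.0
    survival_n_per_group: int = 50
    survival_hazard_ratio: float = 2.0
    survival_censor_rate: float = 0.2


@dataclass
class PipelineConfig:
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    cnv: CNVConfig = field(default_factory=CNVConfig)
    dose_response: DoseResponseConfig = field(default_factory=DoseResponseConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, section: dict, path: str):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(section) - names
            if unknown:
                raise ValueError(f"unknown config keys under {path}: {sorted(unknown)}")
            kwargs = {}
            for f in dataclasses.fields(dc_type):
                if f.name not in section:
                    continue
                val = section[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in _SECTIONS:
                    val = build(_SECTIONS[f.name], val, f"{path}.{f.name}")
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
            return dc_type(**kwargs)

        _SECTIONS = {
            "filter": FilterConfig,
            "cnv": CNVConfig,
            "dose_response": DoseResponseConfig,
            "screen": ScreenConfig,
            "simulate": SimulateConfig,
        }
        return build(cls, data, "pipeline")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
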