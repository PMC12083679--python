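"""Pipeline configuration with the study's published defaults.

Defaults reproduce the printed analysis parameters exactly: 50 um patches,
scaling to the 99th percentile, a fixed fallback split threshold of 0.2, a
scaled-DNA low-signal cutoff of 0.05, and Student's unpaired two-tailed
t-test. Configs load from flat-keyed YAML/JSON and serialize back, so every
report can embed the resolved configuration and its hash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._errors import ConfigurationError
from .io import REQUIRED_MARKERS
from .simulate import SyntheticConfig


@dataclass
class PipelineConfig:
    patch_size_um: float = 50.0
    percentile: float = 99.0
    markers: tuple[str, ...] = REQUIRED_MARKERS
    pooled_scaling: bool = False
    dna_threshold: float = 0.05
    fallback_threshold: float = 0.2
    bandwidth: float | None = None
    search_range: tuple[float, float] = (0.05, 0.95)
    test: str = "student_t"
    per_sample: bool = False
    correction: str | None = None
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["markers"] = list(self.markers)
        d["search_range"] = list(self.search_range)
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "markers" in d:
            d["markers"] = tuple(d["markers"])
        if "search_range" in d:
            d["search_range"] = tuple(d["search_range"])
        if "synth" in d and not isinstance(d["synth"], SyntheticConfig):
            d["synth"] = SyntheticConfig.from_dict(d["synth"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
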