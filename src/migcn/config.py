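"""Run configuration: YAML-serializable settings for the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .extractor import ExtractorConfig
from .gcn import GCNConfig


@dataclass
class SplitConfig:
    test_fraction: float = 0.1
    n_repeats: int = 10
    trial_disjoint: bool = False
    segment_seconds: float = 0.4
    stride_seconds: float | None = None
    trial_seconds: float = 4.0


@dataclass
class RunConfig:
    data_dir: str = "."
    out_dir: str = "runs"
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    graph_data: str = "train"  # or "all" (leaky, faithful to the source setup)
    seed: int = 0
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        for key, cls in (
            ("extractor", ExtractorConfig),
            ("gcn", GCNConfig),
            ("split", SplitConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = cls(**d[key])
        return RunConfig(**d)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
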