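"""Run configuration: one flat JSON document with per-module blocks.

Every command writes its resolved configuration next to its outputs so any
artefact can be regenerated from a single file. All randomness flows from
the top-level seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "."
    synthetic: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    svm: dict = field(default_factory=dict)
    cellularity: dict = field(default_factory=dict)
    cascade: dict = field(default_factory=dict)
    heatmap: dict = field(default_factory=dict)
    agreement: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @staticmethod
    def from_json(path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return RunConfig(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        data = asdict(self)
        for key, value in overrides.items():
            if value is None:
                continue
            if key not in data:
                raise KeyError(f"unknown config key {key!r}")
            data[key] = value
        return RunConfig(**data)
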