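"""Run configuration: the thresholds every filter uses, serialized as JSON."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional


@dataclass
class RunConfig:
    """Pipeline thresholds and bookkeeping.

    Defaults are the stringent panel-construction settings: per-depth-bin
    precision must exceed 0.998 for genotype calls to be retained, repeat
    classes with precision <= 0.997 are dropped, sites missing in more than
    10% of samples are dropped, and sites failing the exact Hardy-Weinberg
    test at p < 1e-5 are dropped.  MAF bin edges: very-rare <= 0.1%,
    rare <= 0.5%, low <= 5%, common above.
    """

    depth_precision_min: float = 0.998
    repeat_precision_min: float = 0.997
    max_missing_fraction: float = 0.10
    hwe_alpha: float = 1e-5
    maf_very_rare: float = 0.001
    maf_rare: float = 0.005
    maf_low: float = 0.05
    projection_fraction: float = 0.90
    min_bin_sites: int = 500
    depth_bin_cap: int = 150
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "depth_precision_min", "repeat_precision_min", "max_missing_fraction",
            "hwe_alpha", "maf_very_rare", "maf_rare", "maf_low",
            "projection_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (self.maf_very_rare < self.maf_rare < self.maf_low):
            raise ValueError("MAF bin edges must be strictly increasing")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)
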