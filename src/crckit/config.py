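"""Run configuration: one serializable object holding every tunable.

All randomness flows from ``seed`` through per-stage derived seeds
(hash of master seed and stage name), so adding a stage never perturbs
the randomness of earlier stages.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .census import CensusConfig
from .classify import GroupConfig
from .detect import DetectionConfig
from .domains import DomainConfig


@dataclass
class ScenarioConfig:
    """What the simulate stage builds."""

    genome_len: int = 400_000
    gc: float = 0.38
    n_complete: int = 12
    n_decoys: int = 6
    n_nonautonomous: int = 6
    max_age_years: float = 2.0e6
    rate: float = 1.3e-8
    kappa: float = 2.0
    tandem_array: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "crc_run"
    genome_fasta: str | None = None  # detect real input instead of simulating
    log_level: str = "INFO"
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    domains: DomainConfig = field(default_factory=DomainConfig)
    groups: GroupConfig = field(default_factory=GroupConfig)
    census: CensusConfig = field(default_factory=CensusConfig)
    density_window_bp: int = 100_000
    density_step_bp: int = 20_000

    def derived_seed(self, stage: str) -> int:
        return zlib.crc32(f"{self.seed}:{stage}".encode()) & 0x7FFFFFFF

    def to_yaml(self, path):
        d = asdict(self)
        for key in ("detection",):
            for f2 in ("ltr_len_range", "element_len_range", "tsd_len_range"):
                d[key][f2] = list(d[key][f2])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for name, sub in (
            ("scenario", ScenarioConfig),
            ("detection", DetectionConfig),
            ("domains", DomainConfig),
            ("groups", GroupConfig),
            ("census", CensusConfig),
        ):
            if name in kw and isinstance(kw[name], dict):
                sd = dict(kw[name])
                for f2 in ("ltr_len_range", "element_len_range", "tsd_len_range"):
                    if f2 in sd and isinstance(sd[f2], list):
                        sd[f2] = tuple(sd[f2])
                kw[name] = sub(**sd)
        return cls(**kw)
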