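"""Run configuration: YAML round-trip, hashing, provenance stamps.

Every pipeline stage reads its parameters from a :class:`RunConfig`; run
directories record the resolved config plus a version stamp so every
artifact is attributable to a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contrastive import SSMILSchedule
from .evaluate import HeadSchedule
from .ssl_tiles import AugmentationPolicy, EncoderSpec, SSLSchedule
from .synthetic import SyntheticBagConfig, SyntheticImageConfig

__all__ = ["RunConfig", "config_hash", "write_provenance"]

SSL_MODES = ("SSL", "SSLn", "passthrough")


@dataclass
class TilingConfig:
    tile_size: int = 32
    working_magnification: float = 20.0
    tissue_threshold: float = 0.5
    connectivity: int = 8


@dataclass
class RunConfig:
    seed: int = 0
    task: str = "classification"
    ssl_mode: str = "SSL"
    bags: SyntheticBagConfig = field(default_factory=SyntheticBagConfig)
    image: SyntheticImageConfig = field(default_factory=SyntheticImageConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    ssl_schedule: SSLSchedule = field(default_factory=SSLSchedule)
    ssmil_schedule: SSMILSchedule = field(default_factory=SSMILSchedule)
    head_schedule: HeadSchedule = field(default_factory=HeadSchedule)

    def __post_init__(self):
        if self.ssl_mode not in SSL_MODES:
            raise ValueError(f"ssl_mode must be one of {SSL_MODES}")
        self.augmentation.use_neighbor = self.ssl_mode == "SSLn"

    # ------------------------------------------------------------- yaml I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly: tuples -> lists handled by asdict? (it keeps tuples)
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                    "bags", "image", "tiling", "augmentation", "encoder",
                    "ssl_schedule", "ssmil_schedule", "head_schedule"):
                sub_cls = {
                    "bags": SyntheticBagConfig, "image": SyntheticImageConfig,
                    "tiling": TilingConfig, "augmentation": AugmentationPolicy,
                    "encoder": EncoderSpec, "ssl_schedule": SSLSchedule,
                    "ssmil_schedule": SSMILSchedule, "head_schedule": HeadSchedule,
                }[f.name]
                sub = {k: (tuple(x) if isinstance(x, list) else x)
                       for k, x in v.items()}
                kwargs[f.name] = sub_cls(**sub)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_provenance(run_dir: str | Path, config: RunConfig) -> None:
    """Record the resolved config and version stamp in a run directory."""
    from . import __version__

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    stamp = {"version": __version__, "config_hash": config_hash(config)}
    (run_dir / "provenance.json").write_text(json.dumps(stamp, sort_keys=True))
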