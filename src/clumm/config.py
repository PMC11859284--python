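"""Declarative run configuration (YAML) with schema validation.

Defaults follow the reference training recipe: contrastive pretraining with
batch 64, AdamW at 0.005 under cosine decay for 500 epochs, a 128-d
projector, and a probe trained for 100 epochs at 0.01 with multistep decay
and 5-fold cross-validation.  Unknown keys are rejected by name so typos
fail before any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .contrastive import NTXentConfig, PretrainConfig, ProjectorConfig
from .encoder import EncoderConfig
from .probe import ProbeConfig

__all__ = ["RunConfig", "SynthSection", "OutlierSection", "parse_and_validate", "config_hash"]


@dataclass(frozen=True)
class SynthSection:
    frames_per_class: int = 200
    noise_sd: float = 0.02
    dropout_rate: float = 0.05
    class_names: tuple[str, ...] = ("idle", "lift", "bend")


@dataclass(frozen=True)
class OutlierSection:
    enabled: bool = False
    counts: tuple[int, ...] = (0, 20, 50)
    n_clusters: int = 3
    outlier_motion: str = "overhead_reach"


@dataclass(frozen=True)
class PipelineSection:
    test_fraction: float = 0.38  # held-out labeled share, as in a ~1500/916 split

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "clumm_run"
    synth: SynthSection = field(default_factory=SynthSection)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    projector: ProjectorConfig = field(default_factory=ProjectorConfig)
    ntxent: NTXentConfig = field(default_factory=NTXentConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    outlier: OutlierSection = field(default_factory=OutlierSection)
    pipeline: PipelineSection = field(default_factory=PipelineSection)


_SECTION_TYPES = {
    "synth": SynthSection,
    "augment": AugmentConfig,
    "encoder": EncoderConfig,
    "projector": ProjectorConfig,
    "ntxent": NTXentConfig,
    "pretrain": PretrainConfig,
    "probe": ProbeConfig,
    "outlier": OutlierSection,
    "pipeline": PipelineSection,
}

_LIST_FIELDS = {"milestones", "counts", "class_names", "input_layout"}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section '{section}'")
    coerced = {
        k: tuple(v) if k in _LIST_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**coerced)


def parse_and_validate(source: str | Path | dict | None) -> RunConfig:
    """Load a YAML config file (or dict); missing keys take defaults.

    An empty or absent document yields the full default configuration.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config document must be a mapping")
    top_known = {"seed", "output_dir", *_SECTION_TYPES}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            data = raw[section]
            if not isinstance(data, dict):
                raise ValueError(f"config section '{section}' must be a mapping")
            kwargs[section] = _build_section(cls, data, section)
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration (for artifact headers)."""
    payload = dataclasses.asdict(config)
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
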