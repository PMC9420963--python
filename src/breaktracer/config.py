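"""Pipeline configuration: defaults, file loading, provenance hashing.

Precedence is CLI flags > config file > built-in defaults.  Unknown keys in
a config file are rejected rather than silently ignored, and the effective
configuration (plus its hash) is embedded into every JSON output so a
result can always be traced back to the parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .design import DesignConstraints
from .errors import ValidationError
from .quant import MIN_DROPLETS_PER_WELL, VolumesConfig


@dataclass(frozen=True)
class QCConfig:
    min_droplets_per_well: int = MIN_DROPLETS_PER_WELL
    borderline_max_positives: int = 1  # 0 -> undetectable, 1 -> borderline, >=2 detectable


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConstraints = field(default_factory=DesignConstraints)
    volumes: VolumesConfig = field(default_factory=VolumesConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    flank_len: int = 300
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {
            "tool": "breaktracer",
            "version": __version__,
            "config_hash": self.config_hash,
            "config": self.to_dict(),
        }


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}"
        )
    return cls(**data)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load configuration from YAML or JSON, then apply flag overrides.

    ``overrides`` may address nested keys as ``section__key`` (e.g.
    ``volumes__plasma_volume_mL=1.0``) or the top-level keys directly.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")

    sections = {"design": DesignConstraints, "volumes": VolumesConfig, "qc": QCConfig}
    top_known = {"flank_len", "seed", *sections}
    unknown = set(data) - top_known
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")

    parts: dict = {}
    for name, cls in sections.items():
        parts[name] = dict(data.get(name, {}))
    top = {k: data[k] for k in ("flank_len", "seed") if k in data}

    for key, value in overrides.items():
        if value is None:
            continue
        if "__" in key:
            section, sub = key.split("__", 1)
            if section not in sections:
                raise ValidationError(f"unknown config section {section!r}")
            parts[section][sub] = value
        elif key in ("flank_len", "seed"):
            top[key] = value
        else:
            raise ValidationError(f"unknown config override {key!r}")

    built = {
        name: _build_section(cls, parts[name], name) for name, cls in sections.items()
    }
    return PipelineConfig(**built, **top)
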