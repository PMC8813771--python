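"""Flat stage-prefixed pipeline configuration.

The configuration file is plain text, one ``stage.key = value`` pair per
line (``#`` comments and blank lines ignored). Values are parsed as JSON
literals where possible, falling back to bare strings. Unknown stages or
keys are rejected before any stage runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration files."""


@dataclass
class SimulateParams:
    n_genes: int = 2_000
    dispersed_donor_genes: int = 28
    mu_donor: float = 18.0
    mu_recurrent: float = 2.0
    dispersion: float = 0.02
    detection_prob: float = 0.9
    expression_genes: int = 5_000
    replicates: int = 3
    effect_size_log2FC: float = 2.0
    nb_dispersion: float = 0.1


@dataclass
class MapParams:
    threshold: int = 10
    min_block_run: int = 5
    max_gap_genes: int = 2


@dataclass
class PhenotypeParams:
    check_line: str = "OLESA"
    n_replicates: int = 3


@dataclass
class DgeParams:
    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    fpkm_min: float = 25.0


@dataclass
class PipelineConfig:
    """All stage parameter groups plus global seed/output settings."""

    seed: int = 1
    outdir: str = "saltil_out"
    log_level: str = "INFO"
    simulate: SimulateParams = field(default_factory=SimulateParams)
    map: MapParams = field(default_factory=MapParams)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    dge: DgeParams = field(default_factory=DgeParams)

    _GLOBAL_KEYS = ("seed", "outdir", "log_level")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        pairs: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in pairs:
                raise ConfigError(f"line {lineno}: duplicate key {key!r}")
            pairs[key] = value
        return cls.from_pairs(pairs)

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "PipelineConfig":
        cfg = cls()
        stage_fields = {
            f.name: {sf.name: sf.type for sf in fields(getattr(cfg, f.name))}
            for f in fields(cfg) if f.name not in cls._GLOBAL_KEYS
        }
        for key, raw in pairs.items():
            value = _parse_value(raw)
            if key in cls._GLOBAL_KEYS:
                setattr(cfg, key, value)
                continue
            if "." not in key:
                raise ConfigError(f"unknown key {key!r}")
            stage, param = key.split(".", 1)
            if stage not in stage_fields:
                raise ConfigError(f"unknown stage {stage!r}")
            if param not in stage_fields[stage]:
                raise ConfigError(f"unknown key {param!r} for stage {stage!r}")
            setattr(getattr(cfg, stage), param, value)
        return cfg


def _parse_value(raw: str):
    try:
        return json.loads(raw)
    except (json.JSONDecodeError, ValueError):
        return raw
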