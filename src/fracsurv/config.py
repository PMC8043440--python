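"""Run configuration: YAML-backed, schema-validated before any work starts.

All randomness in a run flows from the single ``seed``; every command writes
a manifest (config hash + seed) next to its outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .synth import GeneratorConfig, paper_like_config

__all__ = ["RunPaths", "RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(Exception):
    """Invalid or unreadable run configuration."""


class RunPaths(BaseModel):
    corpus: Path = Path("corpus.jsonl")
    gold_labels: Path = Path("gold_labels.csv")
    engine_labels: Path = Path("engine_labels.csv")
    out_dir: Path = Path("out")
    fracture_terms: Path | None = None  # None -> packaged resource
    fracture_blocklist: Path | None = None
    triggers: Path | None = None


class RunConfig(BaseModel):
    paths: RunPaths = RunPaths()
    baseline_years: list[int] = Field(default=[2015, 2016, 2017, 2018, 2019])
    test_year: int = 2020
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    seed: int = 0
    generator: GeneratorConfig | None = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.test_year in self.baseline_years:
            raise ValueError("test_year must not be in baseline_years")
        return self

    def generator_config(self) -> GeneratorConfig:
        if self.generator is not None:
            return self.generator
        return paper_like_config(
            seed=self.seed, years=self.baseline_years + [self.test_year]
        )


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``seed`` overrides the file's."""
    try:
        if path is None:
            cfg = RunConfig()
        else:
            with open(path, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
            cfg = RunConfig.model_validate(data)
    except (OSError, yaml.YAMLError, ValidationError) as exc:
        raise ConfigError(str(exc)) from exc
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
        if cfg.generator is not None:
            cfg.generator = cfg.generator.model_copy(update={"seed": seed})
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    payload = json.dumps(
        json.loads(cfg.model_dump_json()), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
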