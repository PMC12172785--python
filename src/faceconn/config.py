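"""Pipeline configuration (validated YAML) and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class StudyConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    n_participants: int = Field(ge=1)
    sessions_per_participant: int | tuple[int, int] = 1
    design_kind: str = "block"
    modulators: tuple[str, ...] = ()
    hormone_covariate: bool = False
    tr: float = Field(default=2.0, gt=0)
    n_scans: int = Field(default=200, ge=2)
    noise_sd: float | None = None

    @field_validator("design_kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("block", "event"):
            raise ValueError(f"design_kind must be 'block' or 'event', got {v!r}")
        return v


class PriorModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    var_a_off: float = 1.0 / 16.0
    var_a_logscale: float = 1.0 / 64.0
    var_b: float = 1.0
    var_c: float = 1.0
    var_eps: float = 1.0 / 64.0
    var_tau: float = 1.0 / 64.0
    h_mean: float = 4.0
    h_var: float = 4.0


class InversionModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: str = "rk4"
    microtime_ratio: int = Field(default=16, ge=1)
    max_iter: int = Field(default=96, ge=1)
    tol: float = Field(default=1e-3, gt=0)
    n_starts: int = Field(default=3, ge=1)
    n_jobs: int = 1


class BMSModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    prior_alpha: float = Field(default=1.0, gt=0)
    draws: int = Field(default=100_000, ge=1000)


class TruthModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sd_a: float = Field(default=0.1, ge=0)
    sd_b: float = Field(default=0.25, ge=0)
    sd_c: float = Field(default=0.25, ge=0)


class PipelineConfig(BaseModel):
    """Schema-validated configuration for the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    studies: list[StudyConfigModel] = Field(default_factory=list)  # empty: defaults
    truth: TruthModel = Field(default_factory=TruthModel)
    priors: PriorModel = Field(default_factory=PriorModel)
    inversion: InversionModel = Field(default_factory=InversionModel)
    bms: BMSModel = Field(default_factory=BMSModel)
    alpha: float = Field(default=0.05, gt=0, le=1)
    criterion: str = "f"

    @field_validator("criterion")
    @classmethod
    def _crit(cls, v):
        if v not in ("f", "aic", "bic"):
            raise ValueError(f"criterion must be one of f/aic/bic, got {v!r}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)

    def content_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """Checksums + seeds sufficient to re-run any stage bit-identically."""

    def __init__(self, config: PipelineConfig):
        from importlib.metadata import version
        try:
            pkg_version = version("faceconn")
        except Exception:
            pkg_version = "unknown"
        self.doc = {"config_hash": config.content_hash(),
                    "config": config.model_dump(mode="json"),
                    "package_version": pkg_version,
                    "seed": config.seed,
                    "stages": {}}

    def record(self, stage: str, paths: list[Path]) -> None:
        self.doc["stages"][stage] = {str(p): file_checksum(p) for p in sorted(paths)}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.doc, indent=1))
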