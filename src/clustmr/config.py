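"""Validated run configuration (JSON on disk, pydantic in memory)."""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .exceptions import ConfigurationError

__all__ = ["RunConfig", "ClusteringSettings", "MRSettings", "MRPair", "load_config", "stage_seed"]


class ClusteringSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_range: tuple[int, int] = (2, 8)
    n_restarts: int = Field(100, ge=1)
    max_iter: int = Field(300, ge=1)
    tol: float = Field(1e-8, gt=0)
    standardize: bool = False
    gap_b: int = Field(100, ge=10)
    gap_restarts: int = Field(10, ge=1)


class MRSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    se_mode: str = "multiplicative_random"
    n_boot: int = Field(1000, ge=100)
    level: float = Field(0.95, gt=0, lt=1)

    @field_validator("se_mode")
    @classmethod
    def _se_mode(cls, v):
        if v not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown se_mode {v!r}")
        return v


class MRPair(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    exposure: Path
    outcome: Path


class RunConfig(BaseModel):
    """Everything a pipeline run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    panel: Path
    traits: dict[str, Path]  # tables used for the z-matrix and GRS
    outcomes: dict[str, Path] = {}  # tables used for GRS only
    mr_pairs: list[MRPair] = []
    column_map: dict[str, str] = {}
    seed: int = Field(0, ge=0, lt=2**31)
    alpha: float = Field(0.05, gt=0, lt=1)
    eaf_window: float = Field(0.08, ge=0, le=0.5)
    r2_min: float = Field(0.5, ge=0, le=1)
    max_missing: float = Field(0.25, ge=0, le=1)
    palindrome_policy: str = "infer_by_eaf"
    clustering: ClusteringSettings = ClusteringSettings()
    mr: MRSettings = MRSettings()

    @field_validator("palindrome_policy")
    @classmethod
    def _policy(cls, v):
        if v not in ("drop", "infer_by_eaf", "keep"):
            raise ValueError(f"unknown palindrome_policy {v!r}")
        return v

    def resolve_paths(self, base: Path) -> "RunConfig":
        """Interpret relative paths against the config file's directory."""

        def fix(p: Path) -> Path:
            return p if p.is_absolute() else base / p

        return self.model_copy(
            update={
                "panel": fix(self.panel),
                "traits": {k: fix(v) for k, v in self.traits.items()},
                "outcomes": {k: fix(v) for k, v in self.outcomes.items()},
                "mr_pairs": [
                    MRPair(label=p.label, exposure=fix(p.exposure), outcome=fix(p.outcome))
                    for p in self.mr_pairs
                ],
            }
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
    return cfg.resolve_paths(path.parent)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: stages can be rerun independently."""
    return (zlib.crc32(f"{stage}:{master_seed}".encode()) ^ master_seed) % (2**31)
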