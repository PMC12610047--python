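"""Run configuration: schema, validation, seed fan-out.

A run is described by a YAML file validated against a pydantic schema.
Every randomized stage receives an explicit seed derived deterministically
from the single global seed via ``stage_seed`` (a SeedSequence hash keyed
by the stage name), so re-running the same config reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError


class SynthStage(BaseModel):
    n_subjects: int = Field(6, ge=1)
    load_kg: float = Field(10.0, ge=0)
    cycles: int = Field(2, ge=1)
    imbalance_n_fraction: float = Field(0.5, gt=0, lt=1)


class BalanceStage(BaseModel):
    target_count_rule: str | int = "median_class"
    noise_sd_fraction: float = Field(0.05, gt=0)
    max_ratio: float = Field(1.1, ge=1)


class TrainStage(BaseModel):
    arch: str = "bilstm"
    hidden_units: int = Field(32, ge=1)
    max_epochs: int = Field(30, ge=1)
    batch_size: int = Field(128, ge=1)
    initial_lr: float = Field(1e-3, gt=0)
    lr_drop_factor: float = Field(0.1, gt=0, le=1)
    lr_drop_period: int = Field(10, ge=1)
    l2: float = Field(1e-4, ge=0)


class EvalStage(BaseModel):
    protocol: str = Field("split", pattern="^(split|loso)$")


class RunConfig(BaseModel):
    seed: int = 0
    out_dir: str = "runs/demo"
    log_level: str = "INFO"
    synth: SynthStage = SynthStage()
    balance: BalanceStage = BalanceStage()
    train: TrainStage = TrainStage()
    eval: EvalStage = EvalStage()

    model_config = {"extra": "forbid"}


class SchemaError(ValueError):
    """Config does not validate; message carries the JSON-pointer path."""


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        pointers = [
            "/" + "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        ]
        raise SchemaError("invalid config: " + "; ".join(pointers)) from exc


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonicalized config (order-independent)."""
    canon = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global
    seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
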