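"""Layered run configuration: defaults < JSON file < CLI overrides.

Unknown keys are rejected and all validation problems are reported at once;
the merged config is serialized next to every artifact for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .model import PROFILES

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # model
    profile: str = "toy"
    max_len: int | None = None
    # training
    loss_name: str = "similarity"
    epochs: int = 60
    batch_size: int = 32
    anchors_per_batch: int = 8
    learning_rate: float = 1e-3
    scaling_factor: float = 20.0
    margin: float = 1.0
    pos_threshold: float = 0.5
    shape_weight: float = 1.0
    validation_fraction: float = 0.1
    grad_clip: float = 1.0
    # ground-truth metric
    fp_radius: int = 2
    fp_bits: int = 2048
    # misc
    seed: int = 0
    n_references: int = 10
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if self.profile not in PROFILES:
            problems.append(f"profile must be one of {sorted(PROFILES)}")
        if self.loss_name not in ("vanilla", "triplet", "similarity"):
            problems.append("loss_name must be vanilla|triplet|similarity")
        if self.batch_size < 2:
            problems.append("batch_size must be >= 2")
        if not 0 < self.anchors_per_batch < self.batch_size:
            problems.append("need 0 < anchors_per_batch < batch_size")
        if self.scaling_factor <= 0:
            problems.append("scaling_factor must be > 0")
        if self.margin < 0:
            problems.append("margin must be >= 0")
        if not 0 < self.validation_fraction < 1:
            problems.append("validation_fraction must be in (0, 1)")
        if self.fp_radius < 0 or self.fp_bits < 1:
            problems.append("fingerprint params must be non-negative/positive")
        if self.epochs < 1:
            problems.append("epochs must be >= 1")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    def to_json(self) -> str:
        payload = asdict(self)
        payload["schema_version"] = SCHEMA_VERSION
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Merge defaults, an optional JSON file, and CLI overrides (highest)."""
    known = {f.name for f in fields(RunConfig)}
    merged: dict = {}
    if path is not None:
        try:
            raw = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed JSON in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be an object: {path}")
        raw.pop("schema_version", None)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged.update(raw)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in known:
            raise ConfigError(f"unknown config key: {key}")
        merged[key] = value
    try:
        cfg = RunConfig(**merged)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    logger.info("effective config: %s", cfg.to_json().replace("\n", " "))
    return cfg
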