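"""Run configuration and logging helpers.

The config file is a flat key: value text document (YAML-compatible) whose
keys mirror :class:`RunConfig`. CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("calproscreen")


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class RunConfig:
    cutoff_his: float = 9.0          # Å, His Cα census radius around the metal
    cutoff_coordination: float = 3.0  # Å, donor-atom coordination distance
    auc_window: tuple[float, float] = (0.0, 13.0)  # hours
    reference_complex: str = "hTLR4"
    reference_treatment: str = "ENDOTOXIN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_his <= 0 or self.cutoff_coordination <= 0:
            raise ConfigError("distance cutoffs must be positive")
        t0, t1 = self.auc_window
        if not t1 > t0:
            raise ConfigError("auc_window end must exceed start")

    def with_overrides(self, **kwargs) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(self)}
        bad = set(kwargs) - fields
        if bad:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(bad))}")
        values = dataclasses.asdict(self)
        values.update({k: v for k, v in kwargs.items() if v is not None})
        values["auc_window"] = tuple(values["auc_window"])
        return RunConfig(**values)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key: value config file into a RunConfig."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected flat key: value pairs")
    if "auc_window" in data:
        data["auc_window"] = tuple(float(v) for v in data["auc_window"])
    try:
        return RunConfig().with_overrides(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def log_run(stage: str, **params) -> None:
    """Record a pipeline stage's inputs and parameters on the package logger."""
    kv = ", ".join(f"{k}={v}" for k, v in params.items())
    logger.info("%s: %s", stage, kv)
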