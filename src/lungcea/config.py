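"""Configuration files, result serialization and run metadata."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .parameters import ModelParameters, ParameterError, params_from_dict, params_to_dict

__all__ = [
    "RunConfig",
    "load_config",
    "save_params",
    "load_params",
    "parameter_hash",
    "get_logger",
]

MODES = ("deterministic", "psa", "scenarios", "exploratory", "synthetic")


@dataclass
class RunConfig:
    """Settings for one command-line run."""

    mode: str = "deterministic"
    n_sims: int = 1000
    seed: int = 1234
    scenario: Optional[str] = None
    out_dir: Path = field(default_factory=lambda: Path("results"))
    wtp_min: float = 0.0
    wtp_max: float = 150000.0
    wtp_step: float = 1000.0
    plots: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_sims < 1:
            raise ParameterError("n_sims must be at least 1")
        if self.wtp_step <= 0:
            raise ParameterError("wtp_step must be positive")
        self.out_dir = Path(self.out_dir)


def load_config(path: str | Path) -> tuple[ModelParameters, RunConfig]:
    """Read a YAML/JSON configuration holding parameters and run settings."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"configuration {path} is not a mapping")
    params = params_from_dict(data.get("parameters", {}))
    run = RunConfig(**data.get("run", {}))
    return params, run


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Write the full parameter set (values + sampling laws) as YAML."""
    Path(path).write_text(
        yaml.safe_dump({"parameters": params_to_dict(params)}, sort_keys=True)
    )


def load_params(path: str | Path) -> ModelParameters:
    data = yaml.safe_load(Path(path).read_text())
    return params_from_dict(data.get("parameters", data))


def parameter_hash(params: ModelParameters) -> str:
    """Stable short hash of the full parameter set, for run logging."""
    blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def get_logger() -> logging.Logger:
    """Package logger writing to standard error (results go to files only)."""
    logger = logging.getLogger("lungcea")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger
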