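"""Run configuration, result serialisation and the run manifest.

Configs are flat YAML with strict schema checking: unknown keys are
rejected by name, defaults are applied for everything optional, and a
config round-trips through write -> read -> write unchanged. Outputs are
long-format CSV tables plus a JSON manifest recording the config hash,
seed, package version and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    "model": "translation",
    "params_file": None,        # None -> packaged defaults for `model`
    "seed": 0,
    "out_dir": "mirella_out",
    "log_level": "INFO",
    # solver protocol
    "t_end": 10_000.0,
    "rtol": 1e-6,
    "atol": 1e-9,
    # sweep settings
    "eta_min": 1e-2,
    "eta_max": 1e2,
    "eta_points": 20,
    "sigma_values": [0, 1],
    # decay settings
    "decay_eta_values": [0.0, 0.5, 1.0, 2.0, 4.0, 8.0],
    "decay_t_max": 12.0,
    # fit settings
    "lam": 0.001,
    "free_parameters": ["eta_unit", "lambda_TQ", "kappa_ratio"],
    "data_file": None,
}


@dataclass
class RunConfig:
    """Validated settings for a reproducible run."""

    model: str = "translation"
    params_file: str | None = None
    seed: int = 0
    out_dir: str = "mirella_out"
    log_level: str = "INFO"
    t_end: float = 10_000.0
    rtol: float = 1e-6
    atol: float = 1e-9
    eta_min: float = 1e-2
    eta_max: float = 1e2
    eta_points: int = 20
    sigma_values: list = field(default_factory=lambda: [0, 1])
    decay_eta_values: list = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
    decay_t_max: float = 12.0
    lam: float = 0.001
    free_parameters: list = field(default_factory=lambda: list(_DEFAULTS["free_parameters"]))
    data_file: str | None = None

    def __post_init__(self):
        if self.model not in ("translation", "degradation"):
            raise ConfigError(f"model must be translation or degradation, got {self.model!r}")
        if self.eta_min < 0 or self.eta_max <= self.eta_min:
            raise ConfigError("eta grid bounds must satisfy 0 <= eta_min < eta_max")
        if self.lam < 0:
            raise ConfigError("lam must be >= 0")

    @property
    def eta_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.eta_min), np.log10(self.eta_max),
                           self.eta_points)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run config; unknown keys are named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    return RunConfig(**merged)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: dict, out_dir: str | Path, config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write result tables as CSV plus a JSON run manifest.

    ``tables`` maps a short name to a DataFrame; each is written as
    ``<name>.csv`` (header always present, even for empty tables).
    Returns the manifest, which is also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        files[name] = p.name
    manifest = {
        "package": "mirella",
        "version": __version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": config.to_dict() if config else None,
        "config_hash": config_hash(config) if config else None,
        "files": files,
        "written_at_unix": time.time(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
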