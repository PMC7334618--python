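"""Configuration loading, run manifests and deterministic output writing."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .params import CircuitParams

log = logging.getLogger(__name__)

TOP_LEVEL_KEYS = {"params", "calibration", "dose_response", "perturbation", "robustness"}


class ConfigError(ValueError):
    pass


def default_config_path() -> Path:
    return Path(resources.files("narloop") / "data" / "default_config.yaml")


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a run configuration (YAML).

    Unknown top-level sections or parameter names raise a ConfigError naming
    the offending key.
    """
    path = Path(path) if path is not None else default_config_path()
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    unknown = set(cfg) - TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    try:
        params_from_config(cfg)
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"bad params section: {err}") from err
    return cfg


def params_from_config(cfg: dict) -> CircuitParams:
    base = CircuitParams()
    overrides = cfg.get("params") or {}
    if not overrides:
        return base
    unknown = set(overrides) - set(base.to_dict())
    if unknown:
        raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
    return base.copy(**overrides)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run and locate its outputs."""

    stage: str
    config: dict
    params: dict
    seeds: dict = field(default_factory=dict)
    solver: dict = field(default_factory=lambda: {"method": "LSODA",
                                                  "rtol": 1e-8, "atol": 1e-10})
    package_version: str = ""
    outputs: list = field(default_factory=list)
    wall_clock_s: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        return cls(**d)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        _write_json(self.to_dict(), path)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_outputs(tables: dict[str, pd.DataFrame], summaries: dict[str, dict],
                  manifest: RunManifest, out_dir: str | Path) -> list[Path]:
    """Write CSV tables and JSON summaries plus the manifest.

    CSVs carry a header row, '.' decimal separator, UTF-8; JSON is
    pretty-printed with sorted keys so repeated runs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, encoding="utf-8", float_format="%.10g")
        written.append(path)
    for name, obj in summaries.items():
        path = out / f"{name}.json"
        _write_json(obj, path)
        written.append(path)
    manifest.outputs = [str(p.name) for p in written]
    manifest_path = manifest.write(out / "manifest.json")
    log.info("wrote %d output files to %s", len(written) + 1, out)
    return written + [manifest_path]


def start_manifest(stage: str, cfg: dict, params: CircuitParams,
                   seeds: dict | None = None) -> tuple[RunManifest, float]:
    from . import __version__

    return RunManifest(stage=stage, config=cfg, params=params.to_dict(),
                       seeds=seeds or {}, package_version=__version__), time.time()
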