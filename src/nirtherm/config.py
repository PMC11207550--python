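"""Pipeline configuration: YAML/JSON schema, validation, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .synthetic import GeneratorConfig, InstabilityEvent

__all__ = ["PipelineConfig", "load_config", "write_manifest"]

_GENERATOR_FIELDS = set(GeneratorConfig.__dataclass_fields__)


@dataclass
class ScreeningConfig:
    components: tuple[int, ...] = (2, 3, 4)
    k_mad: float = 5.0
    detect: bool = True
    manual_overrides: dict[int, list[int]] = field(default_factory=dict)


@dataclass
class CalibrationConfig:
    h_max: int = 10
    centering_mode: str = "pooled"

    def __post_init__(self) -> None:
        if self.centering_mode not in ("per_phantom", "pooled"):
            raise ConfigError(f"unknown centering_mode {self.centering_mode!r}")
        if self.h_max < 1:
            raise ConfigError("h_max must be >= 1")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    output_dir: Path = Path("nirtherm_out")
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Stable hash of the full configuration for the run manifest."""
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, (GeneratorConfig, ScreeningConfig, CalibrationConfig, PipelineConfig, InstabilityEvent)):
        return {k: _as_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _build_generator(section: dict, seed: int) -> GeneratorConfig:
    unknown = set(section) - _GENERATOR_FIELDS
    if unknown:
        raise ConfigError(f"unknown generator fields: {sorted(unknown)}")
    kwargs = dict(section)
    events = kwargs.pop("instability_events", [])
    kwargs["instability_events"] = tuple(
        InstabilityEvent(**ev) if isinstance(ev, dict) else InstabilityEvent(*ev)
        for ev in events
    )
    if "wavelength_grid_nm" in kwargs:
        kwargs["wavelength_grid_nm"] = tuple(float(v) for v in kwargs["wavelength_grid_nm"])
    kwargs.setdefault("seed", seed)
    return GeneratorConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) pipeline configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"generator", "screening", "calibration", "output_dir", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    scr = raw.get("screening", {})
    manual = {int(k): [int(i) for i in v] for k, v in scr.get("manual_overrides", {}).items()}
    try:
        cfg = PipelineConfig(
            generator=_build_generator(raw.get("generator", {}), seed),
            screening=ScreeningConfig(
                components=tuple(scr.get("components", (2, 3, 4))),
                k_mad=float(scr.get("k_mad", 5.0)),
                detect=bool(scr.get("detect", True)),
                manual_overrides=manual,
            ),
            calibration=CalibrationConfig(**raw.get("calibration", {})),
            output_dir=Path(raw.get("output_dir", "nirtherm_out")),
            seed=seed,
            log_level=str(raw.get("log_level", "INFO")),
        )
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return cfg


def write_manifest(cfg: PipelineConfig, out_dir: Path, stage: str) -> Path:
    """Record provenance (config hash, seed, library versions) for one stage."""
    from . import __version__

    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "nirtherm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
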