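"""Pipeline configuration: one structured YAML file, strict keys.

Unknown keys are rejected with the offending key named (and the nearest
valid key suggested); type errors name the key and the expected type.
Command-line flags override file values.
"""
from __future__ import annotations

import dataclasses
import difflib
from pathlib import Path

import yaml

from .qc import QCThresholds
from .synthetic_cohort import SimulationConfig
from .ld_blocks import GabrielParams


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class MarkerParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.2
    delta_min: float = 0.3


@dataclasses.dataclass
class ScanParams:
    window_mb: float = 20.0
    n_pcs: int = 10
    n_snps_min: int = 50


@dataclasses.dataclass
class AdmixtureParams:
    k_min: int = 2
    k_max: int = 7
    n_restarts: int = 3
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 1000


@dataclasses.dataclass
class AssociationParams:
    n_pcs: int = 2
    adjusted_groups: tuple = ()
    joint_model: bool = False


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    thresholds: QCThresholds = dataclasses.field(default_factory=QCThresholds)
    markers: MarkerParams = dataclasses.field(default_factory=MarkerParams)
    scan: ScanParams = dataclasses.field(default_factory=ScanParams)
    admixture: AdmixtureParams = dataclasses.field(
        default_factory=AdmixtureParams)
    gabriel: GabrielParams = dataclasses.field(default_factory=GabrielParams)
    association: AssociationParams = dataclasses.field(
        default_factory=AssociationParams)
    diff_missing_flag: str | None = None


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "thresholds": QCThresholds,
    "markers": MarkerParams,
    "scan": ScanParams,
    "admixture": AdmixtureParams,
    "gabriel": GabrielParams,
    "association": AssociationParams,
}

_CASTABLE = {int: (int,), float: (int, float), str: (str,), bool: (bool,)}


def _build_section(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            hint = difflib.get_close_matches(key, fields, n=1)
            suggest = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(
                f"unknown key {key!r} in section {section!r}{suggest}")
        ftype = fields[key].type
        base = {"int": int, "float": float, "str": str, "bool": bool}.get(
            str(ftype).replace("builtins.", ""), None)
        if base is not None:
            allowed = _CASTABLE[base]
            if not isinstance(value, allowed) or (base is not bool
                                                  and isinstance(value, bool)):
                raise ConfigError(
                    f"key {key!r} in section {section!r} expects "
                    f"{base.__name__}, got {type(value).__name__} ({value!r})")
            value = base(value)
        if isinstance(value, list):
            value = tuple(tuple(x) if isinstance(x, list) else x
                          for x in value)
        kwargs[key] = value
    return cls(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Parse a YAML pipeline configuration with defaults filled."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = PipelineConfig()
    for section, payload in data.items():
        if section == "diff_missing_flag":
            if payload is not None and not isinstance(payload, str):
                raise ConfigError("diff_missing_flag expects str")
            cfg.diff_missing_flag = payload
            continue
        if section not in _SECTION_TYPES:
            hint = difflib.get_close_matches(section,
                                             list(_SECTION_TYPES) +
                                             ["diff_missing_flag"], n=1)
            suggest = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown section {section!r}{suggest}")
        if payload is None:
            continue
        if not isinstance(payload, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        setattr(cfg, section,
                _build_section(_SECTION_TYPES[section], payload, section))
    return cfg


def config_echo(cfg: PipelineConfig) -> str:
    """Effective configuration as YAML text (for logs and provenance)."""
    out = {}
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        out[f.name] = dataclasses.asdict(val) if dataclasses.is_dataclass(val) \
            else val
    return yaml.safe_dump(out, sort_keys=True)
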