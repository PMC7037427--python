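"""Pipeline configuration: YAML loading with validation and defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .constants import (
    DEFAULT_ENZYME_CONC_M,
    DEFAULT_PATH_CM,
    DEFAULT_POSE_CUTOFF_A,
    DEFAULT_SUBSTRATE_SERIES_MM,
    DEFAULT_TEMPERATURES_C,
    DEFAULT_WINDOW_S,
    EPSILON_DOPACHROME_M_CM,
    R_GAS,
)
from .exceptions import ConfigError

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Assay constants and analysis settings for the full pipeline."""

    epsilon_M_cm: float = EPSILON_DOPACHROME_M_CM
    path_cm: float = DEFAULT_PATH_CM
    window_s: float = DEFAULT_WINDOW_S
    temperatures_C: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    substrate_series_mM: tuple[float, ...] = DEFAULT_SUBSTRATE_SERIES_MM
    enzyme_conc_M: float = DEFAULT_ENZYME_CONC_M
    pose_cutoff_A: float = DEFAULT_POSE_CUTOFF_A
    #: fixed; a config file may restate it but not change it
    gas_constant: float = R_GAS
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        positive = ("epsilon_M_cm", "path_cm", "window_s", "enzyme_conc_M",
                    "pose_cutoff_A")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"config key {name!r} must be strictly positive")
        if len(set(self.temperatures_C)) != len(self.temperatures_C):
            raise ConfigError("config key 'temperatures_C' must be distinct")
        if any(s <= 0 for s in self.substrate_series_mM):
            raise ConfigError("config key 'substrate_series_mM' must be positive")
        if self.gas_constant != R_GAS:
            raise ConfigError(
                f"config key 'gas_constant' is fixed at {R_GAS} J/(K·mol)"
            )


def load_config(path) -> PipelineConfig:
    """Load a YAML config; missing keys take defaults, unknown keys are
    rejected with their names."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    for key in ("temperatures_C", "substrate_series_mM"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: PipelineConfig, path) -> None:
    data = asdict(config)
    data["temperatures_C"] = list(data["temperatures_C"])
    data["substrate_series_mM"] = list(data["substrate_series_mM"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
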