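"""Run configuration: YAML-backed, schema-validated, defaults applied.

Defaults mirror the analysis conventions of the study system: discard the
first 20% of frames (the last 160 ns of a 200 ns run), 5 blocks for the
local density profile, RDF reference carbons C72/C76/C81 (near the sugar,
mid-chain, near the methyl end).
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Itemised configuration errors."""

    def __init__(self, items: list[str]):
        self.items = items
        super().__init__("invalid configuration:\n" + "\n".join(f"- {i}" for i in items))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowConfig(_Strict):
    discard_fraction: float = Field(0.2, ge=0.0, lt=1.0)
    begin: int | None = Field(None, ge=0)  # absolute frame overrides fraction
    end: int | None = Field(None, ge=1)
    blocks: int = Field(5, ge=1)


class AreaConfig(_Strict):
    enabled: bool = True
    lipids_per_leaflet: int | None = Field(None, ge=1)  # default: from leaflets


class LdpConfig(_Strict):
    enabled: bool = True
    bin_width: float = Field(0.5, gt=0.0)


class RdfConfig(_Strict):
    enabled: bool = True
    carbons: list[str] = Field(default_factory=lambda: ["C72", "C76", "C81"])
    bin_width: float = Field(0.1, gt=0.0)
    r_max: float | None = Field(None, gt=0.0)
    blocks: int = Field(1, ge=1)
    mode: str = Field("3d", pattern="^(3d|2d)$")


class GaucheConfig(_Strict):
    enabled: bool = True
    chains: list[str] = Field(default_factory=lambda: ["sn1"])


class TiltConfig(_Strict):
    enabled: bool = True
    bin_width: float = Field(2.0, gt=0.0, le=180.0)
    chains: list[str] = Field(default_factory=lambda: ["sn1"])
    protrusion_lo: float = Field(70.0, gt=0.0, lt=180.0)
    protrusion_hi: float = Field(180.0, gt=0.0, le=180.0)


class AcfConfig(_Strict):
    enabled: bool = True
    max_lag: int | None = Field(None, ge=2)
    include_rings: bool = True
    chain: str = "sn1"


class RunConfig(_Strict):
    """Full pipeline configuration with defaults applied."""

    trajectory: str
    format: str | None = None
    role_map: str
    out_dir: str = "results/run"
    seed: int = 0
    n_leaflets: int = Field(4, ge=1)
    window: WindowConfig = Field(default_factory=WindowConfig)
    area: AreaConfig = Field(default_factory=AreaConfig)
    ldp: LdpConfig = Field(default_factory=LdpConfig)
    rdf: RdfConfig = Field(default_factory=RdfConfig)
    gauche: GaucheConfig = Field(default_factory=GaucheConfig)
    tilt: TiltConfig = Field(default_factory=TiltConfig)
    acf: AcfConfig = Field(default_factory=AcfConfig)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def validate_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; raise with an itemised error list.

    ``overrides`` (dotted keys not supported; top-level only) beat the file.
    Referenced input paths must exist at validation time.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                data[k] = v
    try:
        cfg = RunConfig(**data)
    except ValidationError as err:
        items = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError(items) from None
    missing = [
        f"{key}: file not found: {val}"
        for key, val in (("trajectory", cfg.trajectory), ("role_map", cfg.role_map))
        if not Path(val).exists()
    ]
    if missing:
        raise ConfigError(missing)
    if cfg.tilt.protrusion_lo >= cfg.tilt.protrusion_hi:
        raise ConfigError(["tilt.protrusion_lo must be below tilt.protrusion_hi"])
    return cfg
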