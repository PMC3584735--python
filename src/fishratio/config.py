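"""Configuration: defaults, YAML loading and validation.

All built-in defaults are the original classifier's operating parameters
(spot definitions, tile rules, nucleus gates, ratio thresholds).  The
spatial calibration is not part of those published parameters; the default
``um_per_px = 0.16`` makes a 71-px tile about 11.4 um across — the size of
one or two tumour nuclei, as the tile-sampling design intends — and should
be overridden with the capture station's true calibration when known.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .core import (
    CEP17_SPOT_PARAMS,
    HER2_SPOT_PARAMS,
    ConfigError,
    NucleusParams,
    SpotParams,
    Thresholds,
    TileParams,
)

__all__ = ["Config", "load_config", "DEFAULT_UM_PER_PX"]

DEFAULT_UM_PER_PX = 0.16


@dataclass(frozen=True)
class PreprocessParams:
    """Spot-enhancement filter scales, um."""

    smoothing_sigma_um: float = 0.1
    tophat_radius_um: float = 0.5
    log_sigma_um: float = 0.1

    def __post_init__(self):
        if min(self.smoothing_sigma_um, self.tophat_radius_um, self.log_sigma_um) <= 0:
            raise ConfigError("preprocessing scales must be positive")


@dataclass(frozen=True)
class HsrParams:
    """HSR area-mode constants: trigger factor and fallback reference area."""

    hsr_factor: float = 4.0
    fallback_ref_area_um2: float = 0.15

    def __post_init__(self):
        if self.hsr_factor <= 1:
            raise ConfigError("hsr_factor must exceed 1")
        if self.fallback_ref_area_um2 <= 0:
            raise ConfigError("fallback_ref_area_um2 must be positive")


@dataclass(frozen=True)
class Config:
    um_per_px: float = DEFAULT_UM_PER_PX
    seed: int = 0
    her2: SpotParams = field(default_factory=lambda: HER2_SPOT_PARAMS)
    cep17: SpotParams = field(default_factory=lambda: CEP17_SPOT_PARAMS)
    tile: TileParams = field(default_factory=TileParams)
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    hsr: HsrParams = field(default_factory=HsrParams)
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")

    def to_dict(self) -> dict:
        """Flat, JSON-serialisable echo of the effective configuration."""
        d = {"um_per_px": self.um_per_px, "seed": self.seed, "synthetic": dict(self.synthetic)}
        for section in ("her2", "cep17", "tile", "nucleus", "thresholds", "preprocess", "hsr"):
            d[section] = dataclasses.asdict(getattr(self, section))
        return d


_SECTION_TYPES = {
    "her2": SpotParams,
    "cep17": SpotParams,
    "tile": TileParams,
    "nucleus": NucleusParams,
    "thresholds": Thresholds,
    "preprocess": PreprocessParams,
    "hsr": HsrParams,
}


def _build_section(name: str, cls, overrides: dict, defaults):
    if not isinstance(overrides, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    base = dataclasses.asdict(defaults)
    base.update(overrides)
    try:
        return cls(**base)
    except ConfigError as e:
        raise ConfigError(f"invalid value in section {name!r}: {e}") from e


def config_from_dict(data: dict | None) -> Config:
    """Build a validated Config from a (possibly partial) nested mapping."""
    data = dict(data or {})
    defaults = Config()
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(name, cls, data.pop(name), getattr(defaults, name))
    if "um_per_px" in data:
        kwargs["um_per_px"] = float(data.pop("um_per_px"))
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if "synthetic" in data:
        syn = data.pop("synthetic")
        if not isinstance(syn, dict):
            raise ConfigError("section 'synthetic' must be a mapping")
        from .synthetic import FieldSpec

        known = {f.name for f in dataclasses.fields(FieldSpec)}
        unknown = set(syn) - known
        if unknown:
            raise ConfigError(f"unknown key(s) in section 'synthetic': {sorted(unknown)}")
        kwargs["synthetic"] = syn
    if data:
        raise ConfigError(f"unknown configuration key(s): {sorted(data)}")
    return Config(**kwargs)


def load_config(path) -> Config:
    """Parse a YAML configuration file; an empty file yields full defaults.

    Unknown keys are rejected by name so typos cannot silently fall back to
    defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(data)
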