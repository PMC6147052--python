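"""Pipeline configuration: one YAML-loadable object bundling every tunable
constant, with validation that rejects unknown keys."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .constants import Constants, MapRules, DEFAULT_REGION_MAP

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    constants: Constants = field(default_factory=Constants)
    map_rules: MapRules = field(default_factory=MapRules)
    region_map: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MAP))
    similarity_map: dict | None = None  # None -> packaged default
    se_rule: str = "linear"
    report_precision: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.se_rule not in ("linear", "quadrature"):
            raise ValueError(f"se_rule must be linear or quadrature, got {self.se_rule!r}")
        if self.report_precision < 0:
            raise ValueError("report_precision must be >= 0")


def _build(cls, payload: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline config from YAML; missing file or None gives defaults.

    Similarity-map keys are written in YAML as "ecozone|class|gas" strings and
    parsed back to tuples.
    """
    if path is None:
        return PipelineConfig()
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    if "constants" in payload:
        kwargs["constants"] = _build(Constants, payload["constants"])
    if "map_rules" in payload:
        mr = dict(payload["map_rules"])
        if "wetland_codes" in mr:
            mr["wetland_codes"] = tuple(mr["wetland_codes"])
        kwargs["map_rules"] = _build(MapRules, mr)
    if "region_map" in payload:
        kwargs["region_map"] = dict(payload["region_map"])
    if "similarity_map" in payload:
        kwargs["similarity_map"] = {
            tuple(k.split("|")): v for k, v in payload["similarity_map"].items()
        }
    for key in ("se_rule", "report_precision", "seed"):
        if key in payload:
            kwargs[key] = payload[key]
    return PipelineConfig(**kwargs)
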