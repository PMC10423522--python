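"""YAML run configuration: filter thresholds, consequence-map overrides,
tiering frequency limits and funnel parameters in one validated object."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .engine import DEFAULT_CONSEQUENCE_MAP, FilterConfig
from .panel import AllelicRequirement, MutationConsequence
from .tiering import DEFAULT_AF_LIMITS


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    tier_af_limits: dict[AllelicRequirement, float] = field(
        default_factory=lambda: dict(DEFAULT_AF_LIMITS)
    )
    min_cnv_size: int = 2000
    funnel_k: int = 4

    def validate(self) -> "RunConfig":
        for req, limit in self.tier_af_limits.items():
            if not (0.0 <= limit <= 1.0):
                raise ConfigError(f"tier af limit for {req.value} outside [0,1]")
        if self.funnel_k < 1:
            raise ConfigError("funnel k must be >= 1")
        if self.min_cnv_size < 0:
            raise ConfigError("min_cnv_size must be >= 0")
        return self


def _filter_from_dict(raw: Mapping[str, Any]) -> FilterConfig:
    consequence_map = dict(DEFAULT_CONSEQUENCE_MAP)
    for mech, terms in (raw.get("consequence_map") or {}).items():
        try:
            key = MutationConsequence(mech)
        except ValueError:
            raise ConfigError(f"unknown mutation consequence {mech!r}") from None
        consequence_map[key] = frozenset(terms)
    try:
        return FilterConfig(
            af_monoallelic=float(raw.get("af_monoallelic", 0.001)),
            af_biallelic=float(raw.get("af_biallelic", 0.05)),
            splice_delta_threshold=float(raw.get("splice_delta_threshold", 0.5)),
            consequence_map=consequence_map,
            canonical_only=bool(raw.get("canonical_only", False)),
            retain_carrier_hets_x=bool(raw.get("retain_carrier_hets_x", False)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; a missing path yields the defaults."""
    if path is None:
        return RunConfig().validate()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    limits = dict(DEFAULT_AF_LIMITS)
    for req, limit in (raw.get("tier_af_limits") or {}).items():
        try:
            limits[AllelicRequirement(req)] = float(limit)
        except ValueError:
            raise ConfigError(f"unknown allelic requirement {req!r}") from None
    return RunConfig(
        filter=_filter_from_dict(raw.get("filter") or {}),
        tier_af_limits=limits,
        min_cnv_size=int(raw.get("min_cnv_size", 2000)),
        funnel_k=int(raw.get("funnel_k", 4)),
    ).validate()
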