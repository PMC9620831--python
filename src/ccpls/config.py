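"""Run configuration: schema, defaults, validation, (de)serialisation.

Every tunable of the pipeline lives here.  Unknown keys are rejected and
all schema violations are reported together rather than first-error-only;
a resolved config (defaults filled in) round-trips through ``to_dict`` /
``from_dict`` unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["Config", "HVGConfig", "PLSConfig", "FilterConfig",
           "ClusterConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class HVGConfig:
    method: str = "cv_residual"  # cv_residual | top_n | all
    quantile: float = 0.90
    top_n: int | None = None
    min_hvgs: int = 1


@dataclass
class PLSConfig:
    folds: int = 10
    c_max: int | None = None  # None -> min(L, 10)


@dataclass
class FilterConfig:
    alpha1: float = 0.05
    alpha2: float = 0.05
    n_perm: int = 999
    step1_scope: str = "gene"  # gene | component


@dataclass
class ClusterConfig:
    kmin: int = 2
    kmax: int = 15
    n_restarts: int = 10
    support_threshold: float = 0.9


@dataclass
class Config:
    seed: int = 0
    normalize: str = "median_log1p"  # median_log1p | none | center
    kernel: str = "exponential"  # exponential | gaussian
    dist0: str | float = "auto_min"  # "auto_min" or a fixed positive value
    min_cells: int = 20
    cell_types: list[str] | None = None  # None -> all types
    hvg: HVGConfig = field(default_factory=HVGConfig)
    pls: PLSConfig = field(default_factory=PLSConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    _SECTIONS = {"hvg": HVGConfig, "pls": PLSConfig, "filter": FilterConfig,
                 "cluster": ClusterConfig}

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Config":
        errors: list[str] = []
        top_fields = {f.name for f in fields(cls)}
        for key in data:
            if key not in top_fields:
                errors.append(f"unknown key {key!r}")
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            sub = data.get(name, {})
            if not isinstance(sub, dict):
                errors.append(f"section {name!r} must be a mapping")
                continue
            valid = {f.name for f in fields(section_cls)}
            for key in sub:
                if key not in valid:
                    errors.append(f"unknown key {name!r}.{key!r}")
            kwargs[name] = section_cls(
                **{k: v for k, v in sub.items() if k in valid}
            )
        for key in top_fields - set(cls._SECTIONS):
            if key in data:
                kwargs[key] = data[key]
        cfg = cls(**kwargs) if not errors else None
        if cfg is not None:
            errors.extend(cfg._validate())
        if errors:
            raise ConfigError(errors)
        return cfg

    def _validate(self) -> list[str]:
        errors = []
        if self.normalize not in {"median_log1p", "none", "center"}:
            errors.append(f"normalize: unknown value {self.normalize!r}")
        if self.kernel not in {"exponential", "gaussian"}:
            errors.append(f"kernel: unknown value {self.kernel!r}")
        if isinstance(self.dist0, str):
            if self.dist0 != "auto_min":
                errors.append("dist0 must be 'auto_min' or a positive number")
        elif not self.dist0 > 0:
            errors.append("dist0 must be positive")
        if self.hvg.method not in {"cv_residual", "top_n", "all"}:
            errors.append(f"hvg.method: unknown value {self.hvg.method!r}")
        if not 0 < self.hvg.quantile < 1:
            errors.append("hvg.quantile must be in (0, 1)")
        if self.hvg.method == "top_n" and not self.hvg.top_n:
            errors.append("hvg.top_n required when hvg.method is 'top_n'")
        if self.pls.folds < 2:
            errors.append("pls.folds must be >= 2")
        if self.filter.n_perm < 1:
            errors.append("filter.n_perm must be >= 1")
        if self.filter.step1_scope not in {"gene", "component"}:
            errors.append(
                f"filter.step1_scope: unknown value {self.filter.step1_scope!r}"
            )
        for a in ("alpha1", "alpha2"):
            v = getattr(self.filter, a)
            if not 0 < v < 1:
                errors.append(f"filter.{a} must be in (0, 1)")
        if not 2 <= self.cluster.kmin <= self.cluster.kmax:
            errors.append("cluster: need 2 <= kmin <= kmax")
        if not 0 < self.cluster.support_threshold <= 1:
            errors.append("cluster.support_threshold must be in (0, 1]")
        if self.min_cells < 3:
            errors.append("min_cells must be >= 3")
        return errors


def parse_config(path: str | Path | None = None,
                 overrides: dict[str, Any] | None = None) -> Config:
    """Load a YAML config file (empty file or ``None`` -> all defaults),
    apply flat overrides, validate."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            if not isinstance(loaded, dict):
                raise ConfigError(["config file must contain a mapping"])
            data = loaded
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return Config.from_dict(data)
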