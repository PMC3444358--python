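"""Configuration loading: code lists, algorithm definitions, generator and
validation settings from a single YAML file with sections
``code_lists``, ``algorithms``, ``validation`` and ``generator``.

A packaged default configuration ships the chosen three-criterion COPD
algorithm with editable (non-canonical) ICD-10/ATC code lists; user
configs are merged over it section by section.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dc_fields
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .casefinding import CaseAlgorithm, Criterion, KIND_CODE_COLUMN
from .errors import ConfigurationError
from .registry import CodeList
from .synthetic import GeneratorConfig

__all__ = [
    "load_config",
    "default_config",
    "build_code_lists",
    "build_algorithm",
    "build_generator_config",
    "config_hash",
    "RunConfig",
]


def default_config() -> dict:
    """The packaged default configuration as a plain dict."""
    text = resources.files("copdfind.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: Path | str | None = None) -> dict:
    """Load a YAML config, merged section-wise over the packaged defaults."""
    cfg = default_config()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        try:
            user = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigurationError(f"invalid YAML in {p}: {e}") from e
        if not isinstance(user, Mapping):
            raise ConfigurationError(f"config root must be a mapping: {p}")
        for section, value in user.items():
            if isinstance(value, Mapping) and isinstance(cfg.get(section), Mapping):
                merged = dict(cfg[section])
                merged.update(value)
                cfg[section] = merged
            else:
                cfg[section] = value
    return cfg


def build_code_lists(cfg: Mapping[str, Any]) -> dict[str, CodeList]:
    section = cfg.get("code_lists")
    if not section:
        raise ConfigurationError("config has no 'code_lists' section")
    out = {}
    for name, spec in section.items():
        patterns = (spec or {}).get("patterns")
        if not patterns:
            raise ConfigurationError(f"code list {name!r}: missing 'patterns'")
        out[name] = CodeList(name, [str(p) for p in patterns])
    return out


def build_algorithm(cfg: Mapping[str, Any], name: str | None = None) -> CaseAlgorithm:
    """Materialize a named algorithm (default: validation.default_algorithm)."""
    algorithms = cfg.get("algorithms") or {}
    if name is None:
        name = (cfg.get("validation") or {}).get("default_algorithm")
        if name is None:
            raise ConfigurationError("no algorithm name given and no default configured")
    if name not in algorithms:
        raise ConfigurationError(
            f"unknown algorithm {name!r}; configured: {sorted(algorithms)}"
        )
    spec = algorithms[name]
    code_lists = build_code_lists(cfg)
    criteria = []
    for c in spec.get("criteria", []):
        kind = c.get("kind")
        cl = None
        if kind in KIND_CODE_COLUMN:
            cl_name = c.get("code_list")
            if cl_name not in code_lists:
                raise ConfigurationError(
                    f"algorithm {name!r}: unknown code_list {cl_name!r}"
                )
            cl = code_lists[cl_name]
        criteria.append(
            Criterion(
                label=str(c.get("label")),
                kind=kind,
                lookback_days=int(c.get("lookback_days", 365)),
                min_count=int(c.get("min_count", 1)),
                distinct_dates=bool(c.get("distinct_dates", False)),
                code_list=cl,
                settings=tuple(c["settings"]) if "settings" in c else None,
                diagnosis_roles=tuple(c["diagnosis_roles"]) if "diagnosis_roles" in c else None,
            )
        )
    return CaseAlgorithm(
        name=name,
        criteria=tuple(criteria),
        min_age_years=int(spec.get("min_age_years", 35)),
        require_alive=bool(spec.get("require_alive", True)),
    )


def build_generator_config(cfg: Mapping[str, Any], **overrides: Any) -> GeneratorConfig:
    section = dict(cfg.get("generator") or {})
    section.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dc_fields(GeneratorConfig)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"generator: unknown field(s) {sorted(unknown)}")
    if "index_date" in section and isinstance(section["index_date"], str):
        section["index_date"] = date.fromisoformat(section["index_date"])
    try:
        return GeneratorConfig(**section)
    except TypeError as e:
        raise ConfigurationError(f"generator: {e}") from e


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable hash of a config dict, for provenance manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class RunConfig:
    """Resolved per-run settings: the merged config plus CLI overrides.

    Flags override file values; file values override packaged defaults.
    """

    def __init__(self, config_path: Path | str | None = None, **overrides: Any):
        self.raw = load_config(config_path)
        self.overrides = {k: v for k, v in overrides.items() if v is not None}
        self.hash = config_hash(self.raw)

    def algorithm(self, name: str | None = None) -> CaseAlgorithm:
        return build_algorithm(self.raw, name or self.overrides.get("algorithm"))

    def generator(self, **kw: Any) -> GeneratorConfig:
        merged = {**{k: v for k, v in self.overrides.items()
                     if k in {f.name for f in dc_fields(GeneratorConfig)}}, **kw}
        return build_generator_config(self.raw, **merged)

    @property
    def validation(self) -> dict:
        return dict(self.raw.get("validation") or {})

    def prevalence_by_band(self) -> dict[str, float]:
        return {str(k): float(v)
                for k, v in (self.validation.get("prevalence_by_band") or {}).items()}
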