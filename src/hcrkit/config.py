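"""Configuration loading (YAML/JSON) with CLI-over-file precedence.

Resolution order: built-in defaults <- config file <- CLI overrides. Unknown
keys are an error (never silently ignored) with a closest-match suggestion.
"""

from __future__ import annotations

import difflib
from dataclasses import fields
from pathlib import Path

import yaml

from .design import DesignConfig
from .offtarget import OfftargetConfig
from .thermo import ThermoConfig

__all__ = ["load_config", "ConfigError"]

#: default matching radius (nm) for the coloc subcommand
DEFAULT_COLOC_RADIUS_NM = 750.0

_SECTIONS = {"thermo": ThermoConfig, "offtarget": OfftargetConfig}
_TOP = DesignConfig


class ConfigError(ValueError):
    pass


def _known_keys(cls) -> list[str]:
    return [f.name for f in fields(cls)]


def _check_keys(d: dict, cls, where: str) -> None:
    known = _known_keys(cls)
    for key in d:
        if key in _SECTIONS and cls is _TOP:
            continue
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r} in {where}{suggestion}")


def load_config(path=None, overrides: dict | None = None) -> DesignConfig:
    """Build a resolved DesignConfig from an optional YAML/JSON file plus
    flat override mappings (CLI flags win over the file).

    Override keys use the dataclass field names; thermo/offtarget fields may
    be given flat (``tm_min_c``) or nested (``{"thermo": {...}}``).
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        data = loaded

    _check_keys(data, _TOP, str(path) if path else "config")
    sections = {name: dict(data.get(name) or {}) for name in _SECTIONS}
    for name, cls in _SECTIONS.items():
        _check_keys(sections[name], cls, f"section {name!r}")
    top = {k: v for k, v in data.items() if k not in _SECTIONS}

    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key in _known_keys(_TOP):
            top[key] = val
        else:
            for name, cls in _SECTIONS.items():
                if key in _known_keys(cls):
                    sections[name][key] = val
                    break
            else:
                all_keys = _known_keys(_TOP) + sum(
                    (_known_keys(c) for c in _SECTIONS.values()), []
                )
                hint = difflib.get_close_matches(key, all_keys, n=1)
                suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ConfigError(f"unknown config key {key!r}{suggestion}")

    try:
        return DesignConfig(
            **top,
            thermo=ThermoConfig(**sections["thermo"]),
            offtarget=OfftargetConfig(**sections["offtarget"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
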