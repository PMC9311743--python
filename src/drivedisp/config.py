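"""Run-configuration files: YAML (or JSON, a YAML subset) mirroring the
:class:`~drivedisp.params.SimParams` field names."""
from __future__ import annotations

from pathlib import Path

import yaml

from .params import SimParams


class ConfigError(ValueError):
    """A configuration file could not be turned into valid parameters."""


def load_config(path: str | Path) -> SimParams:
    """Read a config file; unspecified fields take the natural-condition
    defaults. Unknown fields and out-of-range values raise
    :class:`ConfigError` naming the offending field."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of parameter names")
    try:
        return SimParams.from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(params: SimParams, path: str | Path) -> Path:
    """Write the full parameter set; ``load_config`` of the result is the
    identity."""
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
    return path
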