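"""Configuration files, run manifests and tidy CSV export.

Configs are flat YAML/JSON mappings of the run parameters; unknown keys
are rejected and basic range checks applied, so a manifest plus the
package version suffices to re-run a simulation bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Optional

import yaml

from . import __version__

__all__ = ["CONFIG_SCHEMA", "load_config", "save_config", "write_manifest",
           "trajectory_to_csv"]


def _positive(x):
    return x > 0


def _non_negative(x):
    return x >= 0


# key -> (types, validator or None)
CONFIG_SCHEMA = {
    "dt": ((int, float), _positive),
    "t_end": ((int, float), _positive),
    "t_transient": ((int, float), _non_negative),
    "method": (str, lambda v: v in ("heun", "euler")),
    "seed": (int, _non_negative),
    "record_every": (int, _positive),
    "N": (int, _positive),
    "K": ((int, float), _non_negative),
    "dI": ((int, float), _non_negative),
    "n": (int, _positive),
    "beta": ((int, float), _positive),
    "v_th": ((int, float), None),
    "b": ((int, float), _positive),
    "drive": ((int, float), None),
    "drive_center": ((int, float), None),
    "variant": (str, lambda v: v in ("ml_canonical", "paper_literal")),
    "coupling_form": (str, lambda v: v in ("as_printed", "conductance")),
    "synapse_mode": (str, lambda v: v in ("quasi_static", "ode")),
    "gamma_sign": (str, lambda v: v in ("as_printed", "voltage")),
    "exclude_self": (bool, None),
    "master_seed": (int, _non_negative),
}

DEFAULTS = {
    "dt": 0.05,
    "t_transient": 200.0,
    "method": "heun",
    "seed": 0,
    "record_every": 1,
}


def validate_config(cfg: dict) -> dict:
    """Schema-check a flat mapping; unknown keys and out-of-range values
    raise with the offending key names listed."""
    bad = sorted(set(cfg) - set(CONFIG_SCHEMA))
    if bad:
        raise ValueError(f"unknown config keys: {', '.join(bad)}")
    errors = []
    for key, value in cfg.items():
        types, check = CONFIG_SCHEMA[key]
        if isinstance(value, bool) and types is not bool and not (
                isinstance(types, tuple) and bool in types):
            errors.append(key)
            continue
        if not isinstance(value, types):
            errors.append(key)
            continue
        if check is not None and not check(value):
            errors.append(key)
    if errors:
        raise ValueError(f"invalid config values for: {', '.join(sorted(errors))}")
    return cfg


def load_config(path) -> dict:
    """Load a YAML or JSON config; defaults filled, unknown keys rejected.
    An empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    validate_config(data)
    out = dict(DEFAULTS)
    out.update(data)
    return out


def save_config(cfg: dict, path) -> None:
    validate_config({k: v for k, v in cfg.items() if k in CONFIG_SCHEMA})
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def write_manifest(out_dir, command: str, params: dict,
                   outputs: Optional[list] = None) -> Path:
    """Write the run manifest (command, full parameter record, package
    version, timestamp, output paths) next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "parameters": params,
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": [str(p) for p in (outputs or [])],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def trajectory_to_csv(frame, path) -> Path:
    """Write a tidy trajectory/summary DataFrame to CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
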