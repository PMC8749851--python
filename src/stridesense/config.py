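"""Layered run configuration.

Defaults reproduce the constants of the published algorithm: Madgwick gain
β = 0.043, 500 Hz sampling, a 280 ms pre-toe-off start for the first stride,
a 20 ms / +1 m·s⁻¹ guard on the temporary velocity, 40 Hz low-pass, and
offset-search windows of 20–100 ms (20–160 ms for stride 2).

Configuration is a flat dotted-key namespace.  Precedence: CLI flags >
YAML file > built-in defaults.  Unknown keys are rejected so typos never
silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping, Optional

import yaml

DEFAULTS: dict[str, Any] = {
    "gravity.g": 9.81,
    "madgwick.beta": 0.043,
    "madgwick.use_magnetometer": "auto",   # auto | always | never
    "madgwick.init_window_s": 0.5,
    "events.lowpass_hz": 10.0,
    "events.swing_prominence": 3.0,        # rad/s
    "events.dip_prominence": 1.0,          # rad/s
    "sync.window_s": 5.0,
    "sync.threshold_g": 3.0,
    "zvu.enabled": True,
    "zvu.window_lo_s": 0.020,
    "zvu.window_hi_s": 0.100,
    "zvu.window_hi_stride2_s": 0.160,
    "zvu.guard_m_s": 1.0,
    "zvu.lowpass_hz": 40.0,
    "zvu.filter": "critical",      # critical | butter (zero-phase 2nd order)
    "start.pre_toeoff_s": 0.280,
    "dedrift.linear": False,
    "seed": 1,
    "log_level": "INFO",
}


class RunConfig:
    """Immutable-ish flat configuration with dotted keys."""

    def __init__(self, overrides: Optional[Mapping[str, Any]] = None):
        self._values = dict(DEFAULTS)
        if overrides:
            self.update(overrides)

    def update(self, overrides: Mapping[str, Any]) -> "RunConfig":
        unknown = sorted(set(overrides) - set(DEFAULTS))
        if unknown:
            raise KeyError(f"unknown config keys: {', '.join(unknown)}")
        self._values.update(overrides)
        return self

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self._values.get(key, default)

    def as_dict(self) -> dict[str, Any]:
        return dict(self._values)

    @classmethod
    def from_yaml(cls, path, overrides: Optional[Mapping[str, Any]] = None) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        flat = _flatten(loaded)
        cfg = cls(flat)
        if overrides:
            cfg.update(overrides)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._values, fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the effective configuration, for provenance."""
        blob = json.dumps(self._values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self._values == other._values

    def __repr__(self) -> str:
        return f"RunConfig({self._values!r})"


def _flatten(tree: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    """Allow nested YAML (madgwick: {beta: ...}) as well as flat dotted keys."""
    out: dict[str, Any] = {}
    for k, v in tree.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out
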