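"""Pipeline configuration: a single YAML file with explicit units in key names.

Each CLI subcommand reads its own top-level section.  All quantities carry
units in their key names (``tau_c_ns``, ``frame_interval_ns``,
``temperature_K``) so configurations are auditable.  A SHA-256 hash of the
raw config text is embedded in every output file for provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError
from .observables import KarplusParameters, DEFAULT_KARPLUS
from .states import PRESETS, DualCutoffSpec
from .ensemble import ResidueRange


def load_config(path: str | Path) -> tuple[dict[str, Any], str]:
    """Parse the YAML config; returns ``(config, sha256-of-text)``."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    return cfg, hashlib.sha256(text.encode()).hexdigest()


def section(cfg: dict[str, Any], name: str) -> dict[str, Any]:
    if name not in cfg:
        raise ConfigError(f"config is missing the {name!r} section")
    sec = cfg[name]
    if not isinstance(sec, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    return sec


def require(sec: dict[str, Any], field: str, section_name: str) -> Any:
    if field not in sec or sec[field] is None:
        raise ConfigError(f"config field {section_name}.{field} is required")
    return sec[field]


def karplus_from_config(spec: Any) -> dict[str, KarplusParameters]:
    """``"default"`` or a mapping type -> {A, B, C, delta_deg}."""
    if spec in (None, "default"):
        return dict(DEFAULT_KARPLUS)
    if not isinstance(spec, dict):
        raise ConfigError("karplus must be 'default' or a mapping of coupling types")
    out = {}
    for ctype, p in spec.items():
        try:
            out[ctype] = KarplusParameters(
                A=float(p["A"]), B=float(p["B"]), C=float(p["C"]),
                delta_deg=float(p["delta_deg"]), coupling_type=ctype,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"karplus.{ctype}: expected A, B, C, delta_deg ({exc})") from exc
    return out


def dual_cutoff_from_config(spec: Any) -> DualCutoffSpec:
    """A preset name or an explicit segment list."""
    if isinstance(spec, str):
        if spec not in PRESETS:
            raise ConfigError(
                f"unknown dual-cutoff preset {spec!r}; available: {sorted(PRESETS)}"
            )
        return PRESETS[spec]
    if isinstance(spec, dict) and "segments" in spec:
        try:
            segments = tuple(
                (
                    ResidueRange(int(s["first"]), int(s["last"])),
                    float(s["fold_threshold_A"]),
                    float(s["unfold_threshold_A"]),
                )
                for s in spec["segments"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(
                f"dual-cutoff segments need first, last, fold_threshold_A, unfold_threshold_A ({exc})"
            ) from exc
        return DualCutoffSpec(segments=segments, reference=str(spec.get("reference", "")))
    raise ConfigError("dual_cutoff must be a preset name or a mapping with 'segments'")
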