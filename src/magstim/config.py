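"""YAML configuration loading, validation, and run manifests.

Conventions: YAML configs with a fixed key schema (unknown keys are
rejected by name); CSV files are comma-separated, '.' decimal, UTF-8, with
a mandatory header row.  Every CLI run writes a manifest recording the
package version, seed, and a hash of the configuration, so any output can
be re-derived from config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError
from .fieldsim import APPARATUS, CoilArraySpec, CoilSpec, RegionSpec

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_coil_config",
    "write_manifest",
]

_RUN_KEYS = {
    "protocol",
    "coil_config",
    "thresholds",
    "arena",
    "output_dir",
    "seed",
    "verbosity",
}


@dataclass(frozen=True)
class RunConfig:
    """Paths and reproducibility settings of one experiment run."""

    protocol: Optional[str] = None
    coil_config: Optional[str] = None
    thresholds: Optional[str] = None
    arena: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    verbosity: int = 1


def load_config(path) -> RunConfig:
    """Load and validate a run config; referenced files must exist."""
    raw = _load_yaml(path)
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    base = Path(path).parent
    for key in ("protocol", "coil_config", "thresholds", "arena"):
        ref = getattr(cfg, key)
        if ref is not None and not (base / ref).exists() and not Path(ref).exists():
            raise ConfigurationError(f"config key {key!r} references missing file {ref!r}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def _load_yaml(path) -> dict:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a YAML mapping")
    return raw


_COIL_KEYS = {
    "inner_radius",
    "radial_build",
    "axial_length",
    "axial_center",
    "turns",
    "current",
    "wire_gauge",
}
_REGION_KEYS = {"shape", "center", "radius", "height", "half_widths"}


def load_coil_config(path) -> tuple:
    """Load a coil-apparatus config.

    Either ``preset: <name>`` (one of the published apparatus designs,
    optionally with ``current``) or explicit ``coils:`` and ``regions:``
    sections.  Returns (CoilArraySpec, {name: RegionSpec}, grid_spacing).
    """
    raw = _load_yaml(path)
    unknown = set(raw) - {"preset", "current", "coils", "regions", "grid_spacing"}
    if unknown:
        raise ConfigurationError(f"unknown coil-config key(s): {sorted(unknown)}")
    spacing = float(raw.get("grid_spacing", 1e-3))

    if "preset" in raw:
        name = raw["preset"]
        if name not in APPARATUS:
            raise ConfigurationError(
                f"unknown preset {name!r}; available: {sorted(APPARATUS)}"
            )
        factory = APPARATUS[name]
        array, regions = (
            factory(float(raw["current"])) if "current" in raw else factory()
        )
        return array, regions, spacing

    if "coils" not in raw:
        raise ConfigurationError("coil config needs either 'preset' or 'coils'")
    coils = []
    for i, entry in enumerate(raw["coils"]):
        unknown = set(entry) - _COIL_KEYS
        if unknown:
            raise ConfigurationError(f"coil #{i}: unknown key(s) {sorted(unknown)}")
        coils.append(CoilSpec(**entry))
    regions = {}
    for name, entry in raw.get("regions", {}).items():
        unknown = set(entry) - _REGION_KEYS
        if unknown:
            raise ConfigurationError(f"region {name!r}: unknown key(s) {sorted(unknown)}")
        entry = dict(entry)
        if "center" in entry:
            entry["center"] = tuple(entry["center"])
        if "half_widths" in entry:
            entry["half_widths"] = tuple(entry["half_widths"])
        regions[name] = RegionSpec(name=name, **entry)
    return CoilArraySpec(coils=coils), regions, spacing


def write_manifest(output_dir, seed: int, config_payload: dict) -> Path:
    """Write a JSON manifest (versions, seed, config hash) into output_dir."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("magstim")
    except PackageNotFoundError:
        pkg_version = "unknown"
    blob = json.dumps(config_payload, sort_keys=True, default=str)
    manifest = {
        "magstim_version": pkg_version,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config_payload,
    }
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
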