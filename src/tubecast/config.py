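"""Configuration files and reproducible run manifests.

Human-edited configs are YAML mappings of :class:`~tubecast.engine.SimParams`
field names; unknown keys are rejected rather than silently ignored.  Every
run can emit a JSON manifest carrying the fully resolved parameters, the seed
derivation and SHA-256 checksums of its output files, from which the run is
re-executable bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields
from pathlib import Path

import yaml

from . import __version__
from .arena import ConfigError
from .engine import SimParams

_PARAM_NAMES = {f.name for f in fields(SimParams)}


def load_config(path=None, **overrides) -> SimParams:
    """Build SimParams from an optional YAML file plus keyword overrides.

    With no file and no overrides this yields the study defaults (q=0.3,
    r=0.7, b=1/360, crowding threshold 0.9, stop counts 5700/1350, ...).
    """
    data: dict = {}
    if path is not None:
        try:
            text = Path(path).read_text()
            loaded = yaml.safe_load(text)
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config {path}: {exc}")
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a mapping, "
                              f"got {type(loaded).__name__}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _PARAM_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return SimParams(**data)
    except TypeError as exc:
        raise ConfigError(str(exc))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, params: SimParams, seed_key=(),
                   outputs: dict | None = None) -> dict:
    """Write a JSON manifest of one run; returns the manifest dict."""
    manifest = {
        "tubecast_version": __version__,
        "params": params.to_dict(),
        "seed_key": list(seed_key),
        "outputs": {name: {"path": str(p), "sha256": sha256_file(p)}
                    for name, p in (outputs or {}).items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def params_from_manifest(path) -> SimParams:
    """Recover the resolved SimParams recorded in a manifest."""
    manifest = json.loads(Path(path).read_text())
    return SimParams(**manifest["params"])
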