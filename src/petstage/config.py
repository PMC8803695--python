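"""Configuration loading, schema checks and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from petstage.errors import ConfigurationError


def load_yaml_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data


def build_dataclass(cls, data: dict, name: str | None = None):
    """Instantiate a config dataclass, rejecting unknown keys by name."""
    name = name or cls.__name__
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - fields)
    if unknown:
        raise ConfigurationError(f"{name}: unknown config keys: {', '.join(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"{name}: {exc}") from exc


def merge_overrides(base: dict, overrides: dict) -> dict:
    """Flag overrides win over file values win over defaults."""
    out = dict(base)
    for k, v in overrides.items():
        if v is not None:
            out[k] = v
    return out


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written beside every pipeline run's outputs."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def write(self, out_dir) -> Path:
        from petstage import __version__

        self.version = self.version or __version__
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        payload["config_hash"] = _hash_obj(self.config)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path
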