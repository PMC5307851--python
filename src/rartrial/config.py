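"""YAML/JSON configuration loading for design and scenario objects."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .decisions import DesignSpec
from .exceptions import ConfigError
from .posterior import PriorSpec
from .simulate import DeliveryModel, Scenario

__all__ = [
    "load_design",
    "load_scenario",
    "load_prior",
    "design_to_dict",
    "scenario_to_dict",
    "config_digest",
]


def _read(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping")
    # audit metadata written alongside configs, not constructor fields
    for meta in ("seed", "digest"):
        data.pop(meta, None)
    return data


def _build(cls, data: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {what} fields: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {what} config: {exc}") from exc


def load_design(path: str | Path) -> DesignSpec:
    return _build(DesignSpec, _read(path), "design")


def load_prior(path: str | Path) -> PriorSpec:
    return _build(PriorSpec, _read(path), "prior")


def load_scenario(path: str | Path) -> Scenario:
    data = _read(path)
    if "true_rates" in data:
        data["true_rates"] = tuple(data["true_rates"])
    if "arm_labels" in data:
        data["arm_labels"] = tuple(data["arm_labels"])
    if isinstance(data.get("delivery"), dict):
        data["delivery"] = _build(DeliveryModel, data["delivery"], "delivery model")
    return _build(Scenario, data, "scenario")


def design_to_dict(design: DesignSpec) -> dict:
    return dataclasses.asdict(design)


def scenario_to_dict(scenario: Scenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["true_rates"] = list(scenario.true_rates)
    d["arm_labels"] = list(scenario.arm_labels)
    return d


def config_digest(*objects) -> str:
    """Short stable digest of configuration objects, for audit trails."""
    payload = []
    for obj in objects:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            payload.append(dataclasses.asdict(obj))
        else:
            payload.append(obj)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
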