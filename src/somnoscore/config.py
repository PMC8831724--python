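"""Run configuration: one documented YAML schema covering every default.

The schema mirrors the pipeline stages.  Unknown keys are rejected so a
typo in a config file fails loudly instead of silently using a default.
A single ``master_seed`` deterministically derives per-stage seeds by
hashing the stage name, so any stage can be rerun in isolation and still
see the same random stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .repair import RepairParams
from .staging import MovementParams
from .synth import GenConfig

__all__ = ["RunConfig", "load_config", "dump_default_config", "stage_seed"]


@dataclass
class RunConfig:
    """All pipeline defaults in one place."""

    master_seed: int = 0
    log_level: str = "INFO"
    epoch_length_s: float = 8.0
    duration_s: float = 75600.0          # simulated recording length (21 h)
    n_trees: int = 100
    cv_folds: int = 10
    repair: RepairParams = field(default_factory=RepairParams)
    movement: MovementParams = field(default_factory=MovementParams)
    generator: GenConfig = field(default_factory=GenConfig)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def dump_default_config() -> str:
    """The full default configuration as YAML text."""
    return yaml.safe_dump(_to_plain(asdict(RunConfig())), sort_keys=False)


def _build(cls, defaults: dict, overrides: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config keys under {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in overrides:
            continue
        value = overrides[f.name]
        if f.name in ("repair", "movement", "generator"):
            raise AssertionError  # nested sections handled by caller
        kwargs[f.name] = value
    return kwargs


def load_config(path) -> RunConfig:
    """Load a YAML config file, rejecting unknown keys at any level."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sections = {"repair": RepairParams, "movement": MovementParams, "generator": GenConfig}
    top_kwargs = _build(RunConfig, {}, {k: v for k, v in data.items() if k not in sections},
                        "")
    for name, cls in sections.items():
        sub = data.get(name)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ValueError(f"{path}: section {name!r} must be a mapping")
        sub_kwargs = _build(cls, {}, sub, name)
        # tuples serialize as lists; coerce back for range-valued fields
        for key, value in list(sub_kwargs.items()):
            if isinstance(value, list) and len(value) == 2 and all(
                isinstance(v, (int, float)) for v in value
            ) and key.endswith("_s"):
                sub_kwargs[key] = tuple(value)
        top_kwargs[name] = cls(**sub_kwargs)
    return RunConfig(**top_kwargs)
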