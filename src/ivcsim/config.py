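"""Run-configuration loading (YAML or JSON) for the simulation pipeline."""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

import yaml

from .activation import ScenarioSpec
from .experiments import PipelineConfig
from .geometry import LVDimensions
from .materials import ActiveParams, PassiveParams
from .solver import SolverConfig
from .unloading import UnloadingConfig


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def pipeline_config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    kwargs = {}
    sections = {
        "dims": ("dims", LVDimensions),
        "passive": ("passive", PassiveParams),
        "active": ("active", ActiveParams),
        "solver": ("solver", SolverConfig),
        "unloading": ("unloading", UnloadingConfig),
        "scenario": ("scenario_defaults", ScenarioSpec),
    }
    for key, (attr, cls) in sections.items():
        if key in raw:
            kwargs[attr] = _build(cls, raw.pop(key))
    for key in ("n_circ", "n_long", "n_layers", "target_ivc_ms",
                "calibration_tol_ms", "p_ao"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown configuration keys: {sorted(raw)}")
    return PipelineConfig(**kwargs)


def load_pipeline_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return pipeline_config_from_dict(raw or {})
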