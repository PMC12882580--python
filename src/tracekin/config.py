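"""Run configuration: one YAML-backed object covering every tunable key.

Unknown keys are rejected so typos fail fast; the full effective
configuration is echoed into every report (reproducibility contract).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classification import ClassifierConfig
from .cohort import CohortConfig
from .kinematics import KinematicsConfig
from .preprocessing import PreprocessConfig
from .shapes import DEVICE_PX_PER_MM

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    outlier_k: float = 2.0
    single_day: bool = False
    split_seed: int = 0
    device_px_per_mm: float = DEVICE_PX_PER_MM
    shape_epsilon: dict = field(default_factory=dict)  # per-shape overrides

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "cohort":
            kwargs[f.name] = _build(CohortConfig, value)
        elif f.name == "preprocess":
            kwargs[f.name] = _build(PreprocessConfig, value)
        elif f.name == "kinematics":
            kwargs[f.name] = _build(KinematicsConfig, value)
        elif f.name == "classifier":
            kwargs[f.name] = _build(ClassifierConfig, value)
        else:
            kwargs[f.name] = value
    return RunConfig(**kwargs)
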