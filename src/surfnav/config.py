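"""Run configuration: one validated document of every tunable default.

Unknown keys are rejected so typos cannot silently fall back to defaults.
Every pipeline output embeds the SHA-256 hash of the fully resolved config
together with the master seed, so result files are traceable to the exact
parameters that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .depthsim import NoiseModel
from .phantom import PhantomSpec
from .registration import ICPParams, PipelineConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ExtractionConfig:
    threshold: float = 50.0
    median_window_mm: float = 3.0
    target_faces: int = 100_000
    eye_radius_mm: float = 15.0
    voxel_mm: tuple = (0.5, 0.5, 0.5)
    inside_value: float = 100.0
    outside_value: float = 0.0
    intensity_noise_sd: float = 5.0


@dataclass(frozen=True)
class CameraConfig:
    width: int = 320
    height: int = 288
    hfov_deg: float = 75.0
    distance_mm: float = 420.0
    max_range_mm: float = 1500.0


@dataclass(frozen=True)
class EvaluationConfig:
    accuracy_levels: tuple = (0.5, 1.0, 1.5, 2.0, 2.5)
    repeats: int = 3
    probe_jitter_sd_mm: float = 0.5
    entry_placement_sd_mm: float = 0.0
    n_subjects: int = 15
    skin_shift_mm: float = 3.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    registration: PipelineConfig = field(default_factory=PipelineConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    # --- construction -----------------------------------------------------
    @staticmethod
    def from_dict(doc: dict) -> "RunConfig":
        return _build(RunConfig, doc or {}, path="")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must contain a mapping")
        return RunConfig.from_dict(doc)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed,
            phantom=dataclasses.replace(self.phantom, seed=seed),
            noise=dataclasses.replace(self.noise, seed=seed),
            registration=dataclasses.replace(self.registration, seed=seed),
        )

    # --- provenance -------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        doc = json.dumps(self.to_dict(), sort_keys=True, default=_json_default)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.hash()}


def _json_default(o):
    if isinstance(o, tuple):
        return list(o)
    return str(o)


def _build(cls, doc: dict, path: str):
    if not isinstance(doc, dict):
        raise ConfigError(f"expected mapping at {path or 'top level'}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, val in doc.items():
        f = fields[name]
        sub = _nested_type(f)
        if sub is not None:
            kwargs[name] = _build(sub, val, f"{path}{name}.")
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path or 'top level'}: {exc}") from exc


_NESTED = {PhantomSpec, ExtractionConfig, CameraConfig, EvaluationConfig,
           NoiseModel, PipelineConfig, ICPParams}


def _nested_type(f: dataclasses.Field):
    for t in _NESTED:
        if f.type == t.__name__ or f.type is t:
            return t
    return None
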