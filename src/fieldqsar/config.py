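"""Pipeline configuration: YAML-backed, validated, echoed into manifests.

One master seed fans out to per-stage seeds by fixed documented offsets
(see :func:`stage_seeds`), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .alignment import AlignmentConfig
from .conformers import EnsembleConfig
from .fieldspace import FieldConfig
from .synthdata import BenchmarkSpec
from .validation import SplitSpec

__all__ = ["PipelineConfig", "load_config", "stage_seeds"]

# stage name -> offset added to the master seed
_STAGE_OFFSETS = {
    "benchmark": 0,
    "split": 1,
    "models": 2,
    "screening": 3,
    "hopping": 4,
}


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage seeds derived from the master seed by fixed offsets."""
    return {k: (master_seed + v) % (2 ** 31) for k, v in _STAGE_OFFSETS.items()}


@dataclass
class ModelConfig:
    pls_components: int = 5
    cv_folds: int = 3
    consensus_members: tuple[str, ...] = ("field", "svm")


@dataclass
class ScreeningConfig:
    rmsd_cut: float = 0.75
    feature_tolerance: float = 1.0
    max_conformers: int = 20


@dataclass
class PipelineConfig:
    seed: int = 2021
    n_molecules: int = 200
    noise_sd: float = 0.4
    train_fraction: float = 0.8
    n_strata: int = 10
    ensemble: EnsembleConfig = dataclasses.field(default_factory=EnsembleConfig)
    field: FieldConfig = dataclasses.field(default_factory=FieldConfig)
    alignment: AlignmentConfig = dataclasses.field(default_factory=AlignmentConfig)
    models: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    screening: ScreeningConfig = dataclasses.field(default_factory=ScreeningConfig)

    def benchmark_spec(self) -> BenchmarkSpec:
        return BenchmarkSpec(n_molecules=self.n_molecules,
                             noise_sd=self.noise_sd,
                             seed=stage_seeds(self.seed)["benchmark"])

    def split_spec(self) -> SplitSpec:
        return SplitSpec(train_fraction=self.train_fraction,
                         n_strata=self.n_strata,
                         seed=stage_seeds(self.seed)["split"])

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_SECTION_TYPES = {
    "ensemble": EnsembleConfig,
    "field": FieldConfig,
    "alignment": AlignmentConfig,
    "models": ModelConfig,
    "screening": ScreeningConfig,
}


def _build_section(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected.

    ``overrides`` (flat, e.g. from CLI flags) take precedence over file
    values; None values in overrides are ignored.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            data = loaded
    top_fields = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _SECTION_TYPES:
            if not isinstance(v, dict):
                raise ValueError(f"config section {k} must be a mapping")
            kwargs[k] = _build_section(_SECTION_TYPES[k], v, k)
        else:
            kwargs[k] = v
    cfg = PipelineConfig(**kwargs)
    for k, v in (overrides or {}).items():
        if v is None:
            continue
        if not hasattr(cfg, k):
            raise ValueError(f"unknown override {k}")
        setattr(cfg, k, v)
    return cfg
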