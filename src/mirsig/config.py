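"""Pipeline configuration and per-stage seed derivation."""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml

from .io import MirsigError

#: Pipeline stages in execution order; each gets its own child seed so a
#: stage can be re-run in isolation and reproduce the full-run result.
STAGES = ("simulate", "de_screen", "cox_screen", "normalize", "bagging", "signature", "evaluate")


class ConfigError(MirsigError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the discovery pipeline.

    Defaults mirror the published procedure: 1000 bootstrap resamples,
    10-fold cross-validation with the 1-SE rule, a differential-expression
    screen at FDR < 0.05, a univariate Cox screen at Wald p < 0.1, and a
    two-feature signature.
    """

    seed: int = 0
    B_resamples: int = 1000
    cv_folds: int = 10
    lambda_path_length: int = 100
    lambda_min_ratio: float = 0.01
    de_alpha: float = 0.05
    de_use_fdr: bool = True
    cox_screen_alpha: float = 0.1
    top_k: int = 2
    ties_method: str = "breslow"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.B_resamples < 1:
            raise ConfigError("B_resamples must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.lambda_path_length < 1:
            raise ConfigError("lambda_path_length must be >= 1")
        if not 0 < self.lambda_min_ratio < 1:
            raise ConfigError("lambda_min_ratio must lie in (0,1)")
        for name in ("de_alpha", "cox_screen_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0,1)")
        if self.top_k < 1:
            raise ConfigError("top_k must be a positive integer")
        if self.ties_method not in ("breslow", "efron"):
            raise ConfigError("ties_method must be 'breslow' or 'efron'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Child seed for a named stage, by a fixed counter scheme.

    The global seed and the stage's index in :data:`STAGES` form the spawn
    key, so adding stages never perturbs existing ones.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
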