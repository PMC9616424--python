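"""Declarative pipeline configuration.

A single YAML file (or keyword overrides) drives the end-to-end run; all
randomness flows from one master seed, expanded deterministically per
stage.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    # mining
    min_support: float = 0.0001
    min_confidence: float = 0.6
    max_antecedent_len: int | None = 4
    # split
    split_fraction: float = 0.5
    # semi-supervised loop
    seed_size: int = 35
    max_iterations: int = 100
    # evaluation
    k_folds: int = 5
    # synthetic cohort (used when no transaction file is given)
    n_diseases: int = 141
    n_patients: int = 20000
    n_planted: int = 60
    strength_low: float = 2.0
    strength_high: float = 8.0
    target_n_rules: int = 1000
    target_relevant_fraction: float = 0.613
    # randomness
    master_seed: int = 0
    # paths
    transactions: str | None = None
    labeled_rules: str | None = None
    lexicons: str | None = None
    output_dir: str = "extrae_output"

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must lie in (0, 1]")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError("min_confidence must lie in [0, 1]")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.seed_size < 2:
            raise ValueError("seed_size must be at least 2")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")

    @classmethod
    def from_yaml(cls, path, **overrides: Any) -> "PipelineConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        import zlib

        ss = np.random.SeedSequence(
            [self.master_seed, zlib.crc32(stage.encode("utf-8"))]
        )
        return int(ss.generate_state(1)[0] % (2**31 - 1))
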