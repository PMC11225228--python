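"""Analysis configuration (YAML) and reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class ImbalanceParams:
    distance_penalty: float = 8.0
    max_depth: int = 5
    min_branch_length: int = 1

    def validate(self) -> None:
        if self.distance_penalty <= 1:
            raise ValueError("distance_penalty must be > 1")
        if not self.max_depth >= self.min_branch_length >= 1:
            raise ValueError("need max_depth >= min_branch_length >= 1")


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across the pipeline stages."""

    completeness_fraction: float = 0.5
    metabolite_valid_fraction: float = 2.0 / 3.0
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    qc_multiplier: float = 3.0
    imbalance: ImbalanceParams = field(default_factory=ImbalanceParams)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.imbalance, dict):
            self.imbalance = ImbalanceParams(**self.imbalance)
        for name in ("completeness_fraction", "metabolite_valid_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        self.imbalance.validate()

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_manifest(config: AnalysisConfig, inputs: dict, seed: int) -> dict:
    """Provenance record written alongside every pipeline output."""
    import numpy, scipy, pandas  # noqa: PLC0415

    return {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_hash": config.digest(),
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
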