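"""Run configuration for the end-to-end study pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs of a full simulated study.

    ``lambda_dist`` follows :func:`gaprunner.cohort_sim.make_lambda_sampler`
    tuple syntax, e.g. ``("uniform", 0.0, 1.0)``.
    """

    seed: int = 0
    gaps_per_block: int = 10
    cohort_n: int = 32
    lambda_dist: tuple = ("uniform", 0.0, 1.0)
    train_fraction: float = 0.75
    reps: int = 10_000
    family_alpha: float = 0.05
    airtime: float = 1.0
    include_omission_distances: bool = False

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigurationError("seed must be >= 0")
        if self.gaps_per_block < 1:
            raise ConfigurationError("gaps_per_block must be >= 1")
        if self.cohort_n < 0:
            raise ConfigurationError("cohort_n must be >= 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if not 0.0 < self.family_alpha < 1.0:
            raise ConfigurationError("family_alpha must be in (0, 1)")
        if self.airtime <= 0:
            raise ConfigurationError("airtime must be > 0")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        if "lambda_dist" in data and isinstance(data["lambda_dist"], list):
            data = {**data, "lambda_dist": tuple(data["lambda_dist"])}
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_dist"] = list(self.lambda_dist)
        return d
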