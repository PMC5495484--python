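"""Pipeline configuration: one flat, fully validated set of run parameters.

Defaults follow the published analysis settings: lags 0-5, a 10^3-point
density grid, 50,000 permutations, cover threshold theta = 1e-4, the slow
ant-optimization preset, and K = 1..50 with 3 repetitions.  A configuration
is validated in full before any stage runs, and together with the master
seed it determines every output byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Tuple

import yaml

from .aco import PRESETS, AcoParams
from .entropy import LagConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    lags: Tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    grid_points_per_axis: int = 10
    n_perm: int = 50_000
    block_len: int = 3
    log_base: float = 2.0
    theta: float = 1e-4
    preset: str = "slow"
    k_min: int = 1
    k_max: int = 50
    reps: int = 3
    seed: int = 0
    outdir: str = "influmax_out"
    top_k: int = 24  # top-set size for centrality comparison

    def __post_init__(self) -> None:
        # delegate lag/grid/permutation validation to LagConfig
        self.lag_config()
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}")
        if not (0 < self.theta):
            raise ValueError("theta must be positive")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def lag_config(self) -> LagConfig:
        return LagConfig(
            lags=tuple(self.lags),
            grid_points_per_axis=self.grid_points_per_axis,
            n_perm=self.n_perm,
            block_len=self.block_len,
            log_base=self.log_base,
        )

    def aco_params(self) -> AcoParams:
        return PRESETS[self.preset]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from a flat YAML mapping; kwargs take precedence."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "lags" in raw:
            raw["lags"] = tuple(raw["lags"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["lags"] = list(data["lags"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
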