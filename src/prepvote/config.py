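"""Run configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

DEFAULT_MTRY_GRID = (1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24)
DEFAULT_NTREE_GRID = (500, 1000, 2000, 5000)


@dataclass
class RunConfig:
    """Global knobs shared across pipeline stages.

    ``seed`` is the master seed; every randomized stage derives its own
    independent stream via :func:`stage_seed` so that stages can be re-run
    in isolation without perturbing one another.
    """

    seed: int = 0
    horizon_years: float = 5.0
    split_ratio: float = 0.5
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID
    fdr_alpha: float = 0.05
    top_k_genes: int = 100
    cv_folds: int = 10
    input_dir: str = "."
    output_dir: str = "."

    def __post_init__(self) -> None:
        self.mtry_grid = tuple(int(m) for m in self.mtry_grid)
        self.ntree_grid = tuple(int(n) for n in self.ntree_grid)
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if not self.mtry_grid or not self.ntree_grid:
            raise ValueError("tuning grids must be non-empty")
        if any(m <= 0 for m in self.mtry_grid) or any(n <= 0 for n in self.ntree_grid):
            raise ValueError("grid values must be positive")
        if self.top_k_genes < 1:
            raise ValueError("top_k_genes must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.fdr_alpha <= 1.0):
            raise ValueError("fdr_alpha must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON (YAML is a superset, so one loader suffices)."""
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**payload)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in reports for provenance."""
        body = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, *tokens) -> int:
    """Derive a reproducible per-stage seed from the master seed and tokens.

    Token-keyed (not order-keyed) so that adding or reordering stages does
    not shift the streams of unrelated stages.
    """
    material = json.dumps([int(master_seed), [str(t) for t in tokens]])
    h = hashlib.sha256(material.encode()).digest()
    return int.from_bytes(h[:8], "little") % (2**63)


def stage_rng(master_seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, *tokens))
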