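"""Run configuration and seed derivation.

Configuration can be loaded from YAML or JSON (YAML is a superset);
CLI flags override file values. Every stochastic stage derives its own
child seed from the single global ``rng_seed`` by hashing the stage name,
so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig", "child_seed"]


@dataclass
class PipelineConfig:
    """Pipeline constants; defaults follow the analysis being reproduced."""

    n_components: int = 20
    lowpass_hz: float = 0.08
    cluster_z: float = 2.3
    cluster_alpha: float = 0.05
    edge_alpha: float = 0.05
    n_mc_sims: int = 10000
    n_perm_voxelwise: int = 5000
    gof_close_ratio: float = 0.9
    fisher_z: bool = False
    variance_normalize_stage1: bool = True
    filter_kind: str = "ideal"  # "ideal" | "butterworth"
    filter_confounds_first: bool = False
    run_voxelwise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_components", "n_mc_sims", "n_perm_voxelwise"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
            setattr(self, name, int(getattr(self, name)))
        for name in ("cluster_alpha", "edge_alpha"):
            v = float(getattr(self, name))
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < float(self.gof_close_ratio) <= 1.0:
            raise ValueError("gof_close_ratio must be in (0, 1]")
        if not float(self.lowpass_hz) > 0:
            raise ValueError("lowpass_hz must be positive")
        if self.filter_kind not in ("ideal", "butterworth"):
            raise ValueError(f"unknown filter_kind: {self.filter_kind}")
        self.rng_seed = int(self.rng_seed)

    def validate_tr(self, tr_seconds: float) -> None:
        """Check the low-pass cutoff against the Nyquist frequency."""
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.lowpass_hz >= nyquist:
            raise ValueError(
                f"lowpass_hz={self.lowpass_hz} must be below Nyquist={nyquist}"
            )

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        """Load from a YAML/JSON file; keyword arguments override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | os.PathLike) -> None:
        """Write the effective configuration beside the outputs."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def child_seed(self, stage: str) -> int:
        return child_seed(self.rng_seed, stage)


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 32-bit seed from the global seed.

    The stage name is hashed so that adding or reordering stages never
    shifts another stage's random stream.
    """
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")
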