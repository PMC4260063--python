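"""Pipeline configuration.

A single YAML document drives the whole pipeline. Defaults mirror the
field protocol the simulator emulates: capture the 50 nearest profiles
or all within 2 miles, smooth to a 2-mile bandwidth, flag cells above
mean + 2 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from .errors import InvalidParameterError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    k: int = 50
    r_max: float = 2.0
    bandwidth_mi: float = 2.0
    cell_size: float = 0.1
    kernel: str = "gaussian-truncated"
    n_sd: float = 2.0
    age_bins: tuple[int, ...] = (18, 25, 31)
    weight_mode: str = "standardized"
    total_users: float = 2666.0
    coverage_resolution: float = 0.05
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")
        for name in ("r_max", "bandwidth_mi", "cell_size", "coverage_resolution"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_sd < 0:
            raise InvalidParameterError(f"n_sd must be >= 0, got {self.n_sd}")
        if self.weight_mode not in ("standardized", "raw"):
            raise InvalidParameterError(f"unknown weight_mode {self.weight_mode!r}")
        if self.kernel not in ("gaussian-truncated", "gaussian", "quartic"):
            raise InvalidParameterError(f"unknown kernel {self.kernel!r}")
        self.age_bins = tuple(int(e) for e in self.age_bins)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bins"] = list(self.age_bins)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)
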