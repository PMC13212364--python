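"""Run configuration with strict, human-diffable YAML round-tripping.

A single flat configuration describes one processing run end to end — eps
for temporal clustering, the outlier policy, the aggregation statistic, the
model override, and plotting defaults — so that exporting and re-importing
the file reproduces the processing exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    project_dir: str = "."
    eps_hours: float = 6.0
    outlier_method: str = "iqr"  # iqr | zscore
    outlier_mode: str = "annotate"  # filter | winsorize | annotate
    iqr_k: float = 1.5
    z_threshold: float = 3.0
    cell_factors: list = field(
        default_factory=lambda: ["cultivar", "treatment", "trait", "time_point"]
    )
    aggregation: str = "median"  # median | mean
    model_override: str | None = None  # None | anova | mixed | spline
    alpha: float = 0.05
    density_threshold: int = 2000
    dpi: int = 300

    def __post_init__(self):
        if self.eps_hours <= 0:
            raise ConfigError("eps_hours must be positive")
        if self.outlier_method not in ("iqr", "zscore"):
            raise ConfigError(f"unknown outlier_method {self.outlier_method!r}")
        if self.outlier_mode not in ("filter", "winsorize", "annotate"):
            raise ConfigError(f"unknown outlier_mode {self.outlier_mode!r}")
        if self.aggregation not in ("median", "mean"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.model_override not in (None, "anova", "mixed", "spline"):
            raise ConfigError(f"unknown model_override {self.model_override!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**d)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True, allow_unicode=True))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
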