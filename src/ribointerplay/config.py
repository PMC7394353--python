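"""Pipeline configuration.

One structured config object shared by every stage.  Thresholds follow the
study conventions: regulation calls use |log2 FC| > 1 and BH-adjusted
P < 0.05; corem similarity uses SRCC > 0.4 with P < 0.05 and a
non-significant two-sample KS test; stoichiometry deviations are events
outside the 95% percentile interval at two or more time points.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    fc_threshold: float = 1.0          # log2 units
    alpha: float = 0.05
    n_permutations: int = 1_000_000
    n_bootstrap: int = 10_000
    ci_level: float = 0.95
    min_deviation_events: int = 2
    srcc_threshold: float = 0.4
    abundance_bins: tuple[float, ...] = (10.0, 100.0, 1000.0, 10000.0)
    mean_count_floor: float = 1.0      # genes below -> NA padj, NOT_ASSESSED
    replicate_average: str = "median"  # how replicate TPMs are pooled before TE
    sr_centering: str = "median"       # stoichiometry-ratio centering statistic
    support_threshold: float = 0.95    # bootstrap clade support for class calls
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.abundance_bins = tuple(float(b) for b in self.abundance_bins)
        self.validate()

    def validate(self) -> None:
        for name in ("alpha", "ci_level", "support_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.n_permutations < 1 or self.n_bootstrap < 1:
            raise ValueError("permutation/bootstrap counts must be positive")
        if self.min_deviation_events < 1:
            raise ValueError("min_deviation_events must be positive")
        if list(self.abundance_bins) != sorted(set(self.abundance_bins)):
            raise ValueError("abundance_bins must be strictly increasing")
        if self.replicate_average not in ("median", "mean"):
            raise ValueError("replicate_average must be 'median' or 'mean'")
        if self.sr_centering not in ("median", "mean"):
            raise ValueError("sr_centering must be 'median' or 'mean'")

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global one (stable across runs)."""
        return (int(self.random_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["abundance_bins"] = list(self.abundance_bins)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)
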