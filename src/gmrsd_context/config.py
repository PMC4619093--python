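"""Pipeline configuration: every analysis parameter in one serializable object.

Defaults carry the canonical thresholds of the analysis: +/-10-ORF windows,
domain acceptance at E-value < 0.001 with model coverage > 0.8, neighborhood
annotation at E-value < 1e-3, familywise alpha 0.05 with Bonferroni-adjusted
individual confidence levels, the strict > 0.95 conservation mark, and the
0.8 SH-like support threshold for split collapsing.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    window_k: int = 10
    evalue_domain_accept: float = 0.001
    coverage_min: float = 0.8
    evalue_neighborhood: float = 1e-3
    alpha: float = 0.05
    conservation_threshold: float = 0.95
    support_threshold: float = 0.8
    rank_direction: str = "descending"
    seed: int = 0
    #: keyword overrides for the three synthetic-data specs
    genome_sim: dict = field(default_factory=dict)
    family_sim: dict = field(default_factory=dict)
    tree_sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")
        for name in ("evalue_domain_accept", "evalue_neighborhood"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("coverage_min", "conservation_threshold", "support_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.rank_direction not in ("descending", "ascending"):
            raise ValueError("rank_direction must be 'descending' or 'ascending'")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()
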