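"""Pipeline configuration: every tunable threshold in one place.

Defaults are the analysis settings of the cross-species cSCC methylation
study design this package implements: 8x minimum coverage and 6
methylated reads for RRBS locus filtering, FDR 10% (RRBS) / 5% (array),
a 30% beta difference for "clear" differential methylation, the
15-CpG/200-bp/75%-presence DMR candidate rule, the 10,000 most variable
loci for clustering, detection p 0.01 for array probes, and a 1,500 bp
promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    min_coverage: int = 8
    min_meth_reads: int = 6
    rrbs_fdr: float = 0.10
    array_fdr: float = 0.05
    clear_delta: float = 0.30
    dmr_min_cpgs: int = 15
    dmr_max_span_bp: int = 200
    dmr_min_presence: float = 0.75
    dmr_fdr: float = 0.10
    top_k_loci: int = 10000
    max_detection_p: float = 0.01
    promoter_window_bp: int = 1500
    linkage_method: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.min_meth_reads < 0:
            raise ValueError("invalid read-count thresholds")
        for name in ("rrbs_fdr", "array_fdr", "dmr_fdr", "max_detection_p", "dmr_min_presence"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.clear_delta < 1.0:
            raise ValueError("clear_delta must be in (0, 1)")
        if self.dmr_min_cpgs < 2 or self.dmr_max_span_bp < 1 or self.top_k_loci < 1:
            raise ValueError("invalid DMR/clustering parameters")
        if self.promoter_window_bp < 0:
            raise ValueError("promoter_window_bp must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
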