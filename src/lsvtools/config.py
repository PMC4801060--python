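"""Run configuration with YAML round-trip and documented defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable thresholds of a build/quantify run.

    Defaults are the tool's standard operating point: reliability 2 reads /
    2 positions, quantifiable 10 reads / 3 positions, de novo exon cap
    500 bp, intronic coverage 1.5 over 50 bp windows, eta=1 Jeffreys-style
    prior at V=40 resolution, M=100 bootstrap samples, stack flagging at
    p<=1e-7, and differential selection at P(|dPSI|>0.2)>0.95.
    """

    # builder
    min_reads: int = 2
    min_positions: int = 2
    min_overhang: int = 8
    max_denovo_exon: int = 500
    min_intronic_cov: float = 1.5
    intron_window: int = 50
    evidence_mode: str = "any"
    # quantifier
    quant_min_reads: int = 10
    quant_min_positions: int = 3
    stack_pvalue: float = 1.0e-7
    gc_correction: bool = False
    eta: float = 1.0
    V: int = 40
    dpsi_mixture: list = field(
        default_factory=lambda: [[0.2, 1500.0, 1500.0], [0.3, 75.0, 75.0], [0.5, 1.0, 1.0]]
    )
    M: int = 100
    seed: int = 0
    # selection
    dpsi_thresh: float = 0.2
    confidence: float = 0.95

    def __post_init__(self):
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")
        if not (0 <= self.dpsi_thresh <= 1):
            raise ValueError("dpsi_thresh must be in [0, 1]")
        if self.V < 2 or self.M < 1:
            raise ValueError("V >= 2 and M >= 1 required")

    def prior(self):
        from .quantify import PriorConfig

        return PriorConfig(
            eta=self.eta, V=self.V,
            dpsi_mixture=tuple(tuple(c) for c in self.dpsi_mixture),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
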