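"""Pipeline-wide thresholds.

Every numeric rule used by the detection / reconstruction / classification /
introgression stages lives here so that a run is fully described by one
config object plus a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path


@dataclass
class PipelineConfig:
    """Thresholds for the NUMT discovery and introgression pipeline.

    Defaults follow the published rules: a call needs at least five clipped
    reads; supports within 2 kbp are one cluster; the circular mtDNA
    reference is padded with its first 1000 bp; consensus requires 5x depth;
    sequences shorter than 20 bp or below 5x mean depth are discarded;
    flanking scans use a 20 kbp window and a 0.05 frequency cutoff; phasing
    needs a >2/3 majority and at least three reads; diagnostic-allele hits
    need base quality >= 15 on at least five reads.
    """

    min_clipped_reads: int = 5
    cluster_span: int = 2000
    circular_pad: int = 1000
    min_fragment_coverage: int = 5
    min_sequence_length: int = 20
    min_mean_depth: float = 5.0
    flank_window: int = 20000
    freq_threshold: float = 0.05
    phase_majority: float = float(Fraction(2, 3))
    phase_min_reads: int = 3
    bootstrap_reps: int = 100
    bootstrap_gate: float = 50.0
    rarefaction_reps: int = 100
    diag_min_baseq: int = 15
    diag_min_reads: int = 5
    boundary_gap: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            self.min_clipped_reads, self.cluster_span, self.circular_pad,
            self.min_fragment_coverage, self.min_sequence_length,
            self.min_mean_depth, self.flank_window, self.freq_threshold,
            self.phase_min_reads, self.bootstrap_reps, self.rarefaction_reps,
            self.diag_min_baseq, self.diag_min_reads, self.boundary_gap,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all pipeline thresholds must be positive")
        if not 0.5 < self.phase_majority < 1.0:
            raise ValueError("phase_majority must lie in (0.5, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
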