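"""Analysis configuration shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml


@dataclass
class AnalysisConfig:
    """Knobs of the population analyses.

    analysis_delay_cap_ms
        Imaging analyses only use trials with delays up to this duration
        (longer delays are too rare within single sessions to average).
    half_split_ms
        Boundary between the "early" and "late" halves of the delay used by
        persistence and silencing-recovery analyses.
    min_persistence_delay_ms
        Minimum delay duration for a trial to enter the single-trial
        persistence analysis.
    gamma
        Ridge regularizer added to the covariance when fitting coding
        dimensions; stabilizes the matrix inversion.
    """

    analysis_delay_cap_ms: float = 3200.0
    half_split_ms: float = 1600.0
    min_persistence_delay_ms: float = 2000.0
    gamma: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.half_split_ms < self.analysis_delay_cap_ms:
            raise ValueError("half_split_ms must be below analysis_delay_cap_ms")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
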