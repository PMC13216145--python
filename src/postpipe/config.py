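"""Scoring configuration.

All band edges and point values used by the scoring rules live here so the
cut-off validation can sweep thresholds without touching scoring code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError

#: Attack-duration category edges in hours: <4, [4,24], (24,72], >72.
DEFAULT_DURATION_EDGES = (4.0, 24.0, 72.0)


@dataclass(frozen=True)
class ScoringConfig:
    """Point values, band edges and the diagnostic threshold.

    Attributes
    ----------
    threshold:
        Minimum total score for a pre-existing headache to qualify
        (criterion pathway C); the naive pathway B is diagnostic on its own.
    c3_multi_jump_points:
        Points for a jump of >= 2 attack-duration categories. Default 4.
    lenient_lateralization:
        If True, any non-ipsilateral -> ipsilateral shift scores +2
        (prose variant "toward the aneurysm side"); if False, only the
        strict contralateral -> ipsilateral transition scores.
    """

    threshold: int = 9
    b_naive_points: int = 9
    c1_moderate_points: int = 2
    c1_major_points: int = 4
    c1_moderate_delta: float = 2.0
    c1_major_delta: float = 4.0
    c2_points: int = 2
    lenient_lateralization: bool = False
    c3_single_jump_points: int = 1
    c3_multi_jump_points: int = 4
    duration_edges: tuple[float, float, float] = DEFAULT_DURATION_EDGES
    c4_symptom_points: int = 1
    c4_nausea_points: int = 2
    c5_points: int = 4
    c5_min_extra_days: float = 5.0
    c5_min_relative_increase: float = 0.5
    c6_major_points: int = 4
    c6_moderate_points: int = 2
    c6_major_edge: float = 8.0
    c6_moderate_edge: float = 6.0

    def __post_init__(self):
        if self.threshold < 0:
            raise ConfigurationError("threshold must be non-negative")
        if list(self.duration_edges) != sorted(self.duration_edges):
            raise ConfigurationError("duration_edges must be increasing")
        if self.c6_moderate_edge > self.c6_major_edge:
            raise ConfigurationError("c6 band edges out of order")

    @property
    def max_total(self) -> int:
        """Largest total reachable on the pre-existing (C) pathway."""
        c4_max = 4 * self.c4_symptom_points + self.c4_nausea_points
        return (
            self.c1_major_points
            + self.c2_points
            + self.c3_multi_jump_points
            + c4_max
            + self.c5_points
            + self.c6_major_points
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_edges"] = list(self.duration_edges)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScoringConfig":
        data = dict(data)
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown scoring config keys: {sorted(unknown)}")
        if "duration_edges" in data:
            data["duration_edges"] = tuple(float(x) for x in data["duration_edges"])
        return cls(**data)


def load_scoring_config(path) -> ScoringConfig:
    """Load a ScoringConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return ScoringConfig.from_dict(data)
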