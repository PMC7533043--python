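"""Structured analysis configuration.

Holds the constants the frequency-of-sex calculation needs (per-division
mutation rate ``u``, per-meiosis recombination rate ``r``, inbreeding
coefficient ``F``) together with reference genome lengths used to normalise
population recombination-rate estimates, and the gene-filter thresholds.

``u`` and ``r`` have **no defaults**: they are organism- and study-specific
rates that must be supplied explicitly (silently assuming values would
fabricate biology).  ``F`` defaults to 0.98, the published estimate for wild
*Saccharomyces paradoxus*, which is extremely inbred through selfing and
intratetrad mating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Reference genome lengths (bp) used to express 4*Ne*r per base pair.
#: Keys are population labels; values are the full reference length, not the
#: length of the filtered alignment.
DEFAULT_REFERENCE_LENGTHS = {
    "EU": 11_986_733,
    "UK": 11_986_733,
    "FE": 11_813_124,
}

#: Default inbreeding coefficient for wild S. paradoxus.
DEFAULT_F = 0.98


@dataclass
class AnalysisConfig:
    """Constants shared across the pipeline.

    Parameters
    ----------
    u
        Mutation rate per bp per (mitotic) cell division.
    r
        Recombination rate per bp per meiosis, in Morgans/bp.
    F
        Inbreeding coefficient, ``0 <= F < 1``.
    reference_lengths
        Mapping population label -> reference genome length in bp.
    dedupe_identity_threshold, dedupe_min_hit_length
        Thresholds of the paralog similarity screen.
    """

    u: float
    r: float
    F: float = DEFAULT_F
    reference_lengths: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LENGTHS)
    )
    dedupe_identity_threshold: float = 0.8
    dedupe_min_hit_length: int = 100

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError(f"mutation rate u must be positive, got {self.u}")
        if self.r <= 0:
            raise ValueError(f"recombination rate r must be positive, got {self.r}")
        if not 0.0 <= self.F < 1.0:
            raise ValueError(f"inbreeding coefficient F must be in [0, 1), got {self.F}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "u": self.u,
            "r": self.r,
            "F": self.F,
            "reference_lengths": dict(self.reference_lengths),
            "dedupe_identity_threshold": self.dedupe_identity_threshold,
            "dedupe_min_hit_length": self.dedupe_min_hit_length,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)
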