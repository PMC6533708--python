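"""Run configuration.

All tunable thresholds of the pipeline live in :class:`RunConfig`; the
defaults are the published analysis settings where one exists (30 % identity
across 80 % of the sequence length at E-value 1e-4; 1000 bootstrap
replicates with supports above 250 displayed) and field conventions
otherwise (MCL inflation 1.5).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # similarity filter
    min_identity_pct: float = 30.0
    min_coverage_frac: float = 0.80
    max_evalue: float = 1e-4
    # internal aligner
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    kmer_size: int = 4
    prefilter_frac: float = 0.02
    raw_score_floor: float = 25.0
    # MCL
    inflation: float = 1.5
    max_iterations: int = 100
    epsilon: float = 1e-6
    prune_threshold: float = 1e-5
    # pan/core fits
    closed_exponent_threshold: float = 0.5
    n_permutations: int = 100
    # niche screens
    min_pos_chromosome: int = 4
    min_pos_plasmid: int = 3
    max_neg: int = 0
    # plasmid sharedness
    similar_threshold: float = 0.90
    unique_threshold: float = 0.10
    # phylogeny
    bootstrap_reps: int = 1000
    support_display_min: int = 250
    # misc
    hypothetical_phrase: str = "hypothetical protein"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_coverage_frac", "prefilter_frac",
                     "similar_threshold", "unique_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0,1], got {v}")
        for name in ("min_identity_pct", "max_evalue", "inflation",
                     "max_iterations", "epsilon", "prune_threshold",
                     "gap_open", "gap_extend", "kmer_size",
                     "n_permutations", "bootstrap_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inflation <= 1.0:
            raise ValueError("MCL inflation must be > 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
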