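"""Core domain records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated coding sequence (CDS).

    Coordinates are 1-based inclusive (GenBank convention); ``replicon_type``
    is ``chromosome`` or ``plasmid``; ``sequence`` is an amino-acid string
    over the 20-letter alphabet plus X.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    replicon_type: str
    start: int
    end: int
    strand: str
    product: str
    sequence: str

    def __post_init__(self) -> None:
        if self.replicon_type not in ("chromosome", "plasmid"):
            raise ValueError(
                f"{self.gene_id}: unknown replicon_type {self.replicon_type!r}"
            )
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.gene_id}: invalid residues {sorted(bad)!r} in sequence"
            )


@dataclass
class GenomeMeta:
    """Per-genome metadata: ecological niche, spoiler status, replicons."""

    genome_id: str
    niche_label: str = ""
    spoiler: bool | None = None
    replicon_lengths: dict[str, int] = field(default_factory=dict)
    gc_percent: dict[str, float] = field(default_factory=dict)


@dataclass
class SimilarityHit:
    """One directed pairwise protein comparison.

    ``pct_identity`` is on the 0–100 scale; coverages are fractions of the
    full (unaligned) sequence lengths covered by the local alignment
    footprint. ``evalue`` is None for internally computed hits.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_cov: float
    subject_cov: float
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit {self.query_id}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        for name in ("query_cov", "subject_cov"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} out of range: {v}")
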