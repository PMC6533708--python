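"""Genome summary statistics, group means and the CDS-vs-size association.

Works either on computed annotations (via :func:`summarize_genome`) or on a
pre-tabulated per-genome summary table. Rounding of reported means is
centralized in :func:`column_mean` (round-half-to-even), so every printed
average is decided by one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from brevipan.records import GenomeMeta, ProteinRecord


@dataclass
class GenomeSummaryRow:
    genome_id: str
    chromosome_length_mbp: float
    cds_count: int
    hypothetical_pct: float
    assigned_pct: float
    gc_pct: float | None
    plasmid_count: int
    spoiler: bool | None


def summarize_genome(
    records: list[ProteinRecord],
    meta: GenomeMeta,
    hypothetical_phrase: str = "hypothetical protein",
) -> GenomeSummaryRow:
    """Chromosomal CDS count, hypothetical share and replicon layout for one
    genome. The hypothetical rule is a case-insensitive exact-phrase match
    on the product field."""
    recs = [r for r in records if r.genome_id == meta.genome_id]
    chrom = [r for r in recs if r.replicon_type == "chromosome"]
    if not chrom:
        raise ValueError(f"{meta.genome_id}: no chromosomal CDS")
    phrase = hypothetical_phrase.lower()
    n_hyp = sum(1 for r in chrom if phrase == r.product.strip().lower())
    hyp_pct = 100.0 * n_hyp / len(chrom)
    chrom_reps = {r.replicon_id for r in chrom}
    plasmid_reps = {r.replicon_id for r in recs
                    if r.replicon_type == "plasmid"}
    length_bp = sum(meta.replicon_lengths.get(rep, 0) for rep in chrom_reps)
    if not length_bp:
        length_bp = max(r.end for r in chrom)
    gc = None
    if meta.gc_percent:
        chrom_gc = [v for k, v in meta.gc_percent.items() if k in chrom_reps]
        gc = chrom_gc[0] if chrom_gc else None
    return GenomeSummaryRow(
        genome_id=meta.genome_id,
        chromosome_length_mbp=length_bp / 1e6,
        cds_count=len(chrom),
        hypothetical_pct=hyp_pct,
        assigned_pct=100.0 - hyp_pct,
        gc_pct=gc,
        plasmid_count=len(plasmid_reps),
        spoiler=meta.spoiler,
    )


def summary_frame(rows: list[GenomeSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows]).set_index("genome_id")


def column_mean(
    table: pd.DataFrame,
    column: str,
    subset: list[str] | None = None,
    decimals: int | None = None,
) -> float:
    """Arithmetic mean of one column over a genome subset.

    ``decimals`` applies Python's round-half-to-even; None leaves the mean
    unrounded.
    """
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    if subset is not None:
        if not subset:
            raise ValueError("empty subset")
        missing = set(subset) - set(table.index)
        if missing:
            raise KeyError(f"genomes not in table: {sorted(missing)}")
        values = table.loc[list(subset), column]
    else:
        values = table[column]
    m = float(values.mean())
    return round(m, decimals) if decimals is not None else m


def size_cds_association(
    table: pd.DataFrame,
    length_col: str = "chromosome_length_mbp",
    cds_col: str = "cds_count",
) -> tuple[float, float, float]:
    """OLS of CDS count on chromosome length plus Pearson correlation.

    Returns (slope, intercept, r).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 genomes")
    x = table[length_col].to_numpy(dtype=float)
    y = table[cds_col].to_numpy(dtype=float)
    if float(x.var()) == 0.0:
        raise ValueError("zero variance in chromosome length")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
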