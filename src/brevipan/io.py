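"""Readers and writers for the external formats of the pipeline.

FASTA goes through Bio.SeqIO, tables through pandas, trees through
dendropy. Every reader/writer pair is a bit-exact round trip on valid
inputs; parsers never silently drop rows except the documented self-hit
removal in :func:`read_similarity_tabular` (which is logged with a count).
"""

from __future__ import annotations

import logging

import dendropy
import pandas as pd
from Bio import SeqIO

from brevipan.records import GenomeMeta, ProteinRecord, SimilarityHit

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "gene_id", "genome_id", "replicon_id", "replicon_type",
    "start", "end", "strand", "product",
]

BLAST12_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_protein_fasta(path: str) -> list[tuple[str, str]]:
    """Read a protein FASTA file into (id, sequence) pairs in file order.

    The id is the header token before the first whitespace; sequences are
    uppercased. Duplicate ids and empty sequences are hard errors.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA — first content at line {lineno} "
                        f"does not start with '>'"
                    )
                break
        else:
            return []
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def write_protein_fasta(records, path: str, width: int = 60) -> None:
    """Write (id, sequence) pairs or ProteinRecords as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ProteinRecord):
                name, seq = rec.gene_id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_annotation_table(
    path: str,
    sequences: dict[str, str] | None = None,
    genomes_path: str | None = None,
    sequences_optional: bool = False,
) -> tuple[list[ProteinRecord], list[GenomeMeta]]:
    """Read a TSV annotation table into ProteinRecords plus GenomeMetas.

    Required columns: gene_id, genome_id, replicon_id, replicon_type,
    start, end, strand, product. Optional extra columns ``niche_label`` and
    ``spoiler`` populate genome metadata; alternatively a ``genomes_path``
    sidecar TSV (genome_id, niche_label, spoiler) may be given. When
    ``sequences`` (gene_id -> aa string) is None a placeholder is not
    invented: the column ``sequence`` must then be present in the table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")

    records = []
    for row in df.itertuples(index=False):
        if sequences is not None:
            try:
                seq = sequences[row.gene_id]
            except KeyError:
                raise ValueError(f"{path}: no sequence for gene {row.gene_id!r}")
        elif "sequence" in df.columns:
            seq = row.sequence
        elif sequences_optional:
            seq = "X"  # placeholder for sequence-free table operations
        else:
            raise ValueError(
                f"{path}: no 'sequence' column and no sequences mapping given"
            )
        records.append(ProteinRecord(
            gene_id=row.gene_id, genome_id=row.genome_id,
            replicon_id=row.replicon_id, replicon_type=row.replicon_type,
            start=int(row.start), end=int(row.end), strand=row.strand,
            product=row.product, sequence=seq,
        ))

    meta_by_genome: dict[str, GenomeMeta] = {}
    for rec in records:
        meta_by_genome.setdefault(rec.genome_id, GenomeMeta(rec.genome_id))
    if genomes_path is not None:
        gdf = pd.read_csv(genomes_path, sep="\t", dtype=str, comment="#")
        for row in gdf.itertuples(index=False):
            meta = meta_by_genome.get(row.genome_id)
            if meta is None:
                continue
            meta.niche_label = getattr(row, "niche_label", "") or ""
            sp = getattr(row, "spoiler", None)
            if sp is not None and not pd.isna(sp):
                meta.spoiler = str(sp).strip().lower() in ("1", "true", "yes")
    else:
        for col in ("niche_label", "spoiler"):
            if col in df.columns:
                for row in df.itertuples(index=False):
                    meta = meta_by_genome[row.genome_id]
                    if col == "niche_label":
                        meta.niche_label = row.niche_label
                    else:
                        meta.spoiler = (
                            str(row.spoiler).strip().lower() in ("1", "true", "yes")
                        )
    # a genome present in the table always has >=1 CDS by construction;
    # zero-CDS genomes can only arrive via the sidecar and are rejected there
    return records, [meta_by_genome[g] for g in sorted(meta_by_genome)]


def write_annotation_table(records, metas, path: str,
                           with_sequence: bool = True) -> None:
    rows = []
    meta_by_id = {m.genome_id: m for m in metas}
    for r in records:
        m = meta_by_id.get(r.genome_id)
        row = {
            "gene_id": r.gene_id, "genome_id": r.genome_id,
            "replicon_id": r.replicon_id, "replicon_type": r.replicon_type,
            "start": r.start, "end": r.end, "strand": r.strand,
            "product": r.product,
        }
        if with_sequence:
            row["sequence"] = r.sequence
        if m is not None:
            row["niche_label"] = m.niche_label
            row["spoiler"] = "" if m.spoiler is None else str(m.spoiler).lower()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_similarity_tabular(
    path: str, lengths: dict[str, int] | None = None
) -> list[SimilarityHit]:
    """Read 12-column BLAST tabular output into SimilarityHits.

    Coverage fractions are computed as aln_length over the stored length of
    the named sequence when a ``lengths`` table is supplied (query coverage
    against the query length, subject against the subject); without lengths
    the coverages are left at 1.0 caps only if unavailable — callers that
    filter on coverage must supply lengths. Self-hits (query == subject) are
    dropped and the removal is logged with a count.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST12_COLUMNS,
                     comment="#")
    for col in BLAST12_COLUMNS[2:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    hits: list[SimilarityHit] = []
    n_self = 0
    for row in df.itertuples(index=False):
        if row.query == row.subject:
            n_self += 1
            continue
        if lengths is not None:
            for name in (row.query, row.subject):
                if name not in lengths:
                    raise ValueError(f"{path}: unknown sequence id {name!r}")
            qcov = min(1.0, row.aln_length / lengths[row.query])
            scov = min(1.0, row.aln_length / lengths[row.subject])
        else:
            qcov = scov = 1.0
        hits.append(SimilarityHit(
            query_id=str(row.query), subject_id=str(row.subject),
            pct_identity=float(row.pct_identity),
            aln_length=int(row.aln_length),
            query_cov=qcov, subject_cov=scov,
            score=float(row.bitscore), evalue=float(row.evalue),
        ))
    if n_self:
        logger.info("dropped %d self-hits from %s", n_self, path)
    return hits


def write_similarity_tabular(hits, path: str) -> None:
    """Write SimilarityHits in the 12-column tabular dialect.

    Columns without an internal equivalent (mismatches, gap opens, per-hit
    coordinates) are written as 0; absent E-values as 999 (sentinel used by
    several similarity tools for 'not computed').
    """
    with open(path, "w") as fh:
        for h in hits:
            ev = 999.0 if h.evalue is None else h.evalue
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.aln_length}\t0\t0\t0\t0\t0\t0\t{ev:g}\t{h.score:g}\n"
            )


def read_matrix(path: str) -> pd.DataFrame:
    """Read a families x genomes TSV count matrix (first column = row id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row label {dup!r}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("matrix has duplicate row labels")
    matrix.to_csv(path, sep="\t")


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    """Write Newick with branch lengths; internal node labels carry integer
    bootstrap supports when present."""
    tree.write(path=path, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
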